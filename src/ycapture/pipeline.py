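"""End-to-end orchestration: simulate -> account -> enrich -> complexity -> sex/haplogroup.

A run is driven by a :class:`RunConfig` (loadable from YAML), executes the
four-condition experiment per sample — no enrichment (pre-capture), chrY
capture (YCC), whole-genome capture (WGC), and WGC followed by YCC, the
latter expressed as two consecutive capture rounds — and writes the
fold-enrichment grid, yield and enrichment curves, sex calls, haplogroup
calls, and a manifest recording every seed and a config hash. All stage
seeds derive deterministically from the single run seed, so a repeated run
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import accounting, complexity, enrichment, synthio, ychrom

logger = logging.getLogger(__name__)

CONDITIONS = (enrichment.PRE_CAPTURE, enrichment.YCC, enrichment.WGC, enrichment.WGC_YCC)

CURVE_PAIRS = (
    (enrichment.YCC, enrichment.PRE_CAPTURE),
    (enrichment.WGC_YCC, enrichment.PRE_CAPTURE),
    (enrichment.WGC_YCC, enrichment.WGC),
)


def stage_seed(base_seed: int, *labels: Any) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    key = ":".join([str(base_seed), *map(str, labels)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class SampleConfig:
    """Per-sample library, capture, and sequencing-effort settings."""

    profile: synthio.LibraryProfile
    ycc_capture: synthio.CaptureProfile
    wgc_capture: synthio.CaptureProfile
    n_reads: dict[str, int]
    true_haplogroup: str | None = None


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    seed: int
    output_dir: str
    samples: dict[str, SampleConfig]
    region_spec: dict[str, int]  # reference_length, n_regions, total_target_bp
    n_replicates: int = accounting.DEFAULT_N_REPLICATES
    n_bootstrap: int = complexity.DEFAULT_N_BOOTSTRAP
    effort_grid: tuple[float, float, int] = (1e2, 1e6, 40)  # (lo, hi, n) log-spaced
    chry_name: str = "chrY"
    chrx_name: str = "chrX"
    tree_path: str | None = None
    tree_nodes: int = 25
    genotype_depth: float = 5.0
    genotype_error: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = {
            name: SampleConfig(
                profile=synthio.LibraryProfile(**sc["profile"]),
                ycc_capture=synthio.CaptureProfile(**sc["ycc_capture"]),
                wgc_capture=synthio.CaptureProfile(**sc["wgc_capture"]),
                n_reads=dict(sc["n_reads"]),
                true_haplogroup=sc.get("true_haplogroup"),
            )
            for name, sc in raw.pop("samples").items()
        }
        if "effort_grid" in raw:
            raw["effort_grid"] = tuple(raw["effort_grid"])
        return cls(samples=samples, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # hash the scientific config, not its destination
        blob = yaml.safe_dump(_plain(d), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def demo_config(seed: int, output_dir: str, pool_scale: float = 1.0) -> RunConfig:
    """A reduced-scale two-sample configuration emulating the study design.

    One well-preserved library (1.54% endogenous, ~92 bp fragments) and one
    poorly preserved one (0.03% endogenous, ~66 bp fragments), four
    conditions each. Scale knobs shrink the experiment so a full run takes
    seconds, not hours; relative behaviour (fold-enrichment direction,
    clonality growth, capture complexity loss) is preserved.
    """
    refs = {"chrY": 1_000_000, "chrX": 1_000_000, "autosomes": 10_000_000}
    ycc = synthio.CaptureProfile(
        p_on_target=0.9, p_off_target_y=0.05, p_background=1e-4, length_bias_scale=40.0
    )
    # whole-genome capture enriches endogenous templates but the library stays
    # dominated by environmental molecules, as observed in real WGC libraries
    wgc = synthio.CaptureProfile(
        p_on_target=0.6, p_off_target_y=0.6, p_background=0.3, length_bias_scale=40.0
    )
    n = int(500_000 * pool_scale)
    reads = {c: int(20_000 * pool_scale) for c in CONDITIONS}
    reads[enrichment.PRE_CAPTURE] = int(25_000 * pool_scale)
    reads[enrichment.WGC] = int(25_000 * pool_scale)
    samples = {
        "SIM-A": SampleConfig(
            profile=synthio.LibraryProfile(
                pool_size=n,
                endogenous_fraction=0.0154,
                y_fraction_of_endogenous=0.2,
                fragment_length_mean=92.0,
                fragment_length_sd=15.0,
                min_length=30,
                reference_lengths=dict(refs),
            ),
            ycc_capture=ycc,
            wgc_capture=wgc,
            n_reads=dict(reads),
            true_haplogroup="H3",
        ),
        "SIM-B": SampleConfig(
            profile=synthio.LibraryProfile(
                pool_size=n,
                endogenous_fraction=0.0003,
                y_fraction_of_endogenous=0.2,
                fragment_length_mean=66.0,
                fragment_length_sd=12.0,
                min_length=30,
                reference_lengths=dict(refs),
            ),
            ycc_capture=ycc,
            wgc_capture=wgc,
            n_reads=dict(reads),
            true_haplogroup="H7",
        ),
    }
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        samples=samples,
        region_spec={
            "reference_length": refs["chrY"],
            "n_regions": 100,
            "total_target_bp": 400_000,
        },
        n_bootstrap=20,
        effort_grid=(1e2, 1e6, 30),
        tree_nodes=12,
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def simulate_conditions(
    sample: str, sc: SampleConfig, regions: synthio.TargetRegions, seed: int
) -> dict[str, list[synthio.ReadRecord]]:
    """Build the four condition pools and sequence them."""
    pool = synthio.simulate_molecule_pool(sc.profile, regions, stage_seed(seed, sample, "pool"))
    wg = synthio.whole_genome_regions()
    pools = {
        enrichment.PRE_CAPTURE: pool,
        enrichment.YCC: synthio.simulate_capture(
            pool, regions, sc.ycc_capture, stage_seed(seed, sample, "ycc")
        ),
        enrichment.WGC: synthio.simulate_capture(
            pool, wg, sc.wgc_capture, stage_seed(seed, sample, "wgc")
        ),
    }
    pools[enrichment.WGC_YCC] = synthio.simulate_capture(
        pools[enrichment.WGC], regions, sc.ycc_capture, stage_seed(seed, sample, "wgc+ycc")
    )
    reads = {}
    for cond, p in pools.items():
        n = sc.n_reads[cond]
        if len(p) == 0:
            logger.warning("sample %s condition %s: empty pool, no reads", sample, cond)
            reads[cond] = []
        else:
            reads[cond] = synthio.amplify_and_sequence(p, n, stage_seed(seed, sample, "seq", cond))
        logger.info(
            "stage=simulate sample=%s condition=%s templates=%d reads=%d",
            sample, cond, len(p), len(reads[cond]),
        )
    return reads


def account_sample(
    sample: str,
    reads_by_condition: dict[str, list[synthio.ReadRecord]],
    regions: synthio.TargetRegions,
    config: RunConfig,
) -> dict[str, accounting.ReplicateSummary]:
    """Down-sample all conditions to the minimum retained count and summarize."""
    counts = {c: len(r) for c, r in reads_by_condition.items() if r}
    if not counts:
        raise ValueError(f"sample {sample}: no condition produced reads")
    n = accounting.min_retained_reads(counts)
    summaries = {}
    for cond, reads in reads_by_condition.items():
        replicates = accounting.downsample(
            reads, min(n, len(reads)), config.n_replicates,
            stage_seed(config.seed, sample, "ds", cond),
        )
        metrics = [
            accounting.library_metrics(rep, regions, chry_name=config.chry_name)
            for rep in replicates
        ]
        summaries[cond] = accounting.summarize_replicates(metrics)
        logger.info(
            "stage=account sample=%s condition=%s n=%d on_target_mean=%.1f",
            sample, cond, n, summaries[cond].mean["on_target_unique"] or 0.0,
        )
    return summaries


def complexity_sample(
    sample: str,
    reads_by_condition: dict[str, list[synthio.ReadRecord]],
    regions: synthio.TargetRegions,
    config: RunConfig,
) -> tuple[dict[str, complexity.YieldCurve], dict[tuple[str, str], complexity.EnrichmentCurve]]:
    """Yield curves (bootstrap median/variance) and enrichment curves per sample."""
    lo, hi, npts = config.effort_grid
    grid = np.logspace(np.log10(lo), np.log10(hi), int(npts))
    curves: dict[str, complexity.YieldCurve] = {}
    for cond, reads in reads_by_condition.items():
        mapped = [r for r in reads if r.reference != synthio.EXOGENOUS_REF]
        on_target_raw = accounting.classify_on_target(mapped, regions).on_target
        total = len(reads)
        if not on_target_raw or total == 0:
            logger.warning("sample %s condition %s: no on-target reads; curve omitted", sample, cond)
            continue
        _, hist = accounting.deduplicate(on_target_raw)
        fraction = len(on_target_raw) / total
        curves[cond] = complexity.bootstrap_yield(
            hist, grid, fraction, config.n_bootstrap,
            stage_seed(config.seed, sample, "boot", cond),
        )
    ecurves = {}
    for c1, c2 in CURVE_PAIRS:
        if c1 in curves and c2 in curves:
            ecurves[(c1, c2)] = complexity.enrichment_curve(curves[c1], curves[c2])
    return curves, ecurves


def sex_sample(
    reads: list[synthio.ReadRecord], config: RunConfig
) -> ychrom.SexResult | None:
    """Ry sex call from unique mapped pre-capture reads."""
    unique, _ = accounting.deduplicate(
        [r for r in reads if r.reference != synthio.EXOGENOUS_REF]
    )
    n_y = sum(1 for r in unique if r.reference == config.chry_name)
    n_x = sum(1 for r in unique if r.reference == config.chrx_name)
    if n_x + n_y == 0:
        return None
    return ychrom.ry_statistic(n_x, n_y)


def haplogroup_sample(
    sample: str, sc: SampleConfig, tree: ychrom.HaplogroupTree, config: RunConfig
) -> ychrom.HaplogroupCall | None:
    if sc.true_haplogroup is None:
        return None
    pileup = synthio.simulate_genotypes(
        tree,
        sc.true_haplogroup,
        config.genotype_depth,
        config.genotype_error,
        stage_seed(config.seed, sample, "genotypes"),
    )
    calls = ychrom.call_haploid_genotypes(
        pileup, seed=stage_seed(config.seed, sample, "haploid")
    )
    return ychrom.assign_haplogroup(calls, tree)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts; returns the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "config_hash": config.config_hash()}
    artifacts: list[str] = []

    def emit(name: str, payload) -> None:
        path = out / name
        if name.endswith(".json"):
            path.write_text(json.dumps(_plain(payload), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(payload)
        artifacts.append(name)

    try:
        regions = synthio.make_target_regions(
            seed=stage_seed(config.seed, "regions"), **config.region_spec
        )
        regions.to_bed(out / "target_regions.bed")
        artifacts.append("target_regions.bed")

        if config.tree_path:
            tree = ychrom.load_haplogroup_tree(config.tree_path)
        else:
            tree = synthio.make_random_tree(config.tree_nodes, stage_seed(config.seed, "tree"))
        ychrom.write_haplogroup_tree(tree, out / "haplogroup_tree.tsv")
        artifacts.append("haplogroup_tree.tsv")

        all_summaries: dict[tuple[str, str], accounting.ReplicateSummary] = {}
        sex_results = {}
        hap_results = {}
        curve_rows = []
        ecurve_rows = []
        for sample, sc in config.samples.items():
            reads = simulate_conditions(sample, sc, regions, config.seed)
            summaries = account_sample(sample, reads, regions, config)
            for cond, summ in summaries.items():
                all_summaries[(sample, cond)] = summ
            curves, ecurves = complexity_sample(sample, reads, regions, config)
            for cond, curve in curves.items():
                for e, m, v in zip(curve.efforts, curve.median, curve.variance):
                    curve_rows.append(f"{sample}\t{cond}\t{e:.1f}\t{m:.4f}\t{v:.6g}")
            for (c1, c2), ec in ecurves.items():
                for e, f in zip(ec.efforts, ec.fold):
                    ecurve_rows.append(f"{sample}\t{c1}\t{c2}\t{e:.1f}\t{f:.4f}")
            sex = sex_sample(reads[enrichment.PRE_CAPTURE], config)
            if sex is not None:
                sex_results[sample] = dataclasses.asdict(sex)
            hap = haplogroup_sample(sample, sc, tree, config)
            if hap is not None:
                hap_results[sample] = dataclasses.asdict(hap)

        table = enrichment.build_enrichment_table(all_summaries)
        emit("enrichment_table.tsv", table.to_csv(sep="\t", index=False))
        emit(
            "metrics.json",
            {
                f"{s}/{c}": {"mean": summ.mean, "ci": summ.ci, "n_replicates": summ.n_replicates}
                for (s, c), summ in all_summaries.items()
            },
        )
        emit(
            "yield_curves.tsv",
            "sample\tcondition\teffort\tmedian\tvariance\n" + "\n".join(curve_rows) + "\n",
        )
        emit(
            "enrichment_curves.tsv",
            "sample\tcondition_1\tcondition_2\teffort\tfold\n" + "\n".join(ecurve_rows) + "\n",
        )
        emit("sex_results.json", sex_results)
        emit("haplogroup_calls.json", hap_results)
    except Exception as exc:  # annotate the failing stage for the caller
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": report["config_hash"],
        "artifacts": sorted(artifacts),
        "stage_seeds": {
            "regions": stage_seed(config.seed, "regions"),
            "tree": stage_seed(config.seed, "tree"),
        },
    }
    emit("manifest.json", manifest)
    report["artifacts"] = sorted(artifacts)
    report["enrichment_table"] = table
    report["sex"] = sex_results
    report["haplogroups"] = hap_results
    return report
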