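"""Published benchmark values for capture-enrichment accounting.

Down-sampled per-library means from a published Y-chromosome
capture-enrichment study of six ancient individuals from the Caribbean
(two from Saint Martin, STM; four from Paso del Indio, Puerto Rico, PI).
Each library was sequenced under four conditions — no enrichment
(pre-capture), Y-chromosome capture (YCC), whole-genome capture (WGC), and
whole-genome capture followed by Y capture (WGC+YCC) — down-sampled ten
times to the per-individual minimum read count, and averaged. ``None``
marks cells where no read of the given class was observed in any replicate
(printed as a dash in the original table).

These numbers are inputs for reproducing the study's derived statistics
(fold-enrichments and on-target percentages); they are not computed here.
"""

from __future__ import annotations

import pandas as pd

SAMPLES = ("STM1", "STM2", "PI174", "PI383", "PI435", "PI437")
CONDITIONS = ("pre-capture", "YCC", "WGC", "WGC+YCC")

#: Down-sampled total reads per individual (equal across conditions).
DOWNSAMPLED_TOTAL_READS: dict[str, int] = {
    "STM1": 68_795,
    "STM2": 30_629,
    "PI174": 159_728,
    "PI383": 107_796,
    "PI435": 41_810,
    "PI437": 56_157,
}

#: Mean unique on-target read counts (10 down-sampling replicates).
ON_TARGET_MEAN: dict[tuple[str, str], float | None] = {
    ("STM1", "pre-capture"): 2.3,
    ("STM2", "pre-capture"): 0.2,
    ("PI174", "pre-capture"): None,
    ("PI383", "pre-capture"): None,
    ("PI435", "pre-capture"): 0.1,
    ("PI437", "pre-capture"): None,
    ("STM1", "YCC"): 16_191.0,
    ("STM2", "YCC"): 1_909.8,
    ("PI174", "YCC"): 17.0,
    ("PI383", "YCC"): 27.0,
    ("PI435", "YCC"): 25.0,
    ("PI437", "YCC"): 12.0,
    ("STM1", "WGC"): 16.8,
    ("STM2", "WGC"): 1.5,
    ("PI174", "WGC"): 0.1,
    ("PI383", "WGC"): 0.1,
    ("PI435", "WGC"): None,
    ("PI437", "WGC"): None,
    ("STM1", "WGC+YCC"): 4_239.5,
    ("STM2", "WGC+YCC"): 222.0,
    ("PI174", "WGC+YCC"): 17.1,
    ("PI383", "WGC+YCC"): 81.3,
    ("PI435", "WGC+YCC"): 109.7,
    ("PI437", "WGC+YCC"): 24.5,
}

#: Mean unique chrY-mapped read counts (10 down-sampling replicates).
CHRY_MEAN: dict[tuple[str, str], float | None] = {
    ("STM1", "pre-capture"): 2.8,
    ("STM2", "pre-capture"): 0.2,
    ("PI174", "pre-capture"): None,
    ("PI383", "pre-capture"): 0.2,
    ("PI435", "pre-capture"): 0.1,
    ("PI437", "pre-capture"): None,
    ("STM1", "YCC"): 16_430.0,
    ("STM2", "YCC"): 1_925.0,
    ("PI174", "YCC"): 17.0,
    ("PI383", "YCC"): 27.0,
    ("PI435", "YCC"): 26.0,
    ("PI437", "YCC"): 12.0,
    ("STM1", "WGC"): 38.8,
    ("STM2", "WGC"): 2.7,
    ("PI174", "WGC"): 0.2,
    ("PI383", "WGC"): 0.1,
    ("PI435", "WGC"): 0.2,
    ("PI437", "WGC"): None,
    ("STM1", "WGC+YCC"): 4_414.0,
    ("STM2", "WGC+YCC"): 236.0,
    ("PI174", "WGC+YCC"): 17.1,
    ("PI383", "WGC+YCC"): 82.5,
    ("PI435", "WGC+YCC"): 111.9,
    ("PI437", "WGC+YCC"): 25.5,
}


def capture_benchmark() -> pd.DataFrame:
    """Benchmark grid as a tidy DataFrame.

    Columns: sample, condition, total_reads (down-sampled), on_target_mean,
    chry_mean. Missing cells are NaN.
    """
    rows = []
    for sample in SAMPLES:
        for condition in CONDITIONS:
            rows.append(
                {
                    "sample": sample,
                    "condition": condition,
                    "total_reads": DOWNSAMPLED_TOTAL_READS[sample],
                    "on_target_mean": ON_TARGET_MEAN[(sample, condition)],
                    "chry_mean": CHRY_MEAN[(sample, condition)],
                }
            )
    return pd.DataFrame(rows)
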