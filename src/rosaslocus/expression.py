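"""FPKM computation and tissue-specificity classification.

Read counts per gene and tissue are converted to FPKM
(count * 1e9 / (library_size * effective_length)), with effective length
taken as the CDS length, and each gene is placed into one of four
mutually exclusive expression categories used to nominate S-locus
candidates: the S-pistil gene is expected to be pistil/ovary-high with at
most low stamen expression, and S-pollen F-box genes stamen-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("pistil_ovary", "stamen", "leaf", "stem", "root")

PISTIL_OVARY_HIGH = "pistil_ovary_high"
STAMEN_ONLY = "stamen_only"
BROAD = "broad"
NOT_EXPRESSED = "not_expressed"

CATEGORIES = (PISTIL_OVARY_HIGH, STAMEN_ONLY, BROAD, NOT_EXPRESSED)


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM values with the inputs that produced them."""

    fpkm: pd.DataFrame
    library_sizes: pd.Series
    lengths: pd.Series


@dataclass
class TissueClassification:
    categories: pd.Series            # gene -> category
    thresholds: dict[str, float] = field(default_factory=dict)


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_sizes: pd.Series) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (library_size * length_nt), per cell."""
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive effective length")
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("every tissue needs a positive library size")
    values = counts.to_numpy(dtype=float) * 1e9
    values /= np.outer(lengths.to_numpy(dtype=float),
                       library_sizes.to_numpy(dtype=float))
    return ExpressionMatrix(
        fpkm=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        library_sizes=library_sizes,
        lengths=lengths,
    )


def classify_tissue_pattern(
    matrix: ExpressionMatrix,
    expressed_threshold: float = 1.0,
    high_threshold: float = 10.0,
    low_threshold: float = 1.0,
) -> TissueClassification:
    """Assign each gene one of four exclusive tissue categories.

    * not_expressed: every tissue below the expressed threshold;
    * stamen_only: stamen expressed, all other tissues below it;
    * pistil_ovary_high: pistil/ovary at or above the high threshold,
      every other non-stamen tissue below the expressed threshold and
      stamen below the high threshold (low stamen expression tolerated);
    * broad: everything else.
    """
    if not low_threshold <= expressed_threshold <= high_threshold:
        raise ValueError("thresholds must satisfy low <= expressed <= high")
    unknown = [c for c in matrix.fpkm.columns if c not in TISSUES]
    if unknown:
        raise ValueError(f"unknown tissue labels {unknown}; expected {TISSUES}")
    missing = [t for t in TISSUES if t not in matrix.fpkm.columns]
    if missing:
        raise ValueError(f"missing tissue columns {missing}")

    out = {}
    for gene, row in matrix.fpkm.iterrows():
        pistil = row["pistil_ovary"]
        stamen = row["stamen"]
        others = [row[t] for t in ("leaf", "stem", "root")]
        if (row[list(TISSUES)] < expressed_threshold).all():
            out[gene] = NOT_EXPRESSED
        elif stamen >= expressed_threshold and pistil < expressed_threshold \
                and all(v < expressed_threshold for v in others):
            out[gene] = STAMEN_ONLY
        elif pistil >= high_threshold and all(v < expressed_threshold for v in others) \
                and stamen < high_threshold:
            out[gene] = PISTIL_OVARY_HIGH
        else:
            out[gene] = BROAD
    return TissueClassification(
        categories=pd.Series(out, name="category"),
        thresholds={
            "expressed": expressed_threshold,
            "high": high_threshold,
            "low": low_threshold,
        },
    )
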