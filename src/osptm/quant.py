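"""Label-free quantitation by standardized spectral counting.

Counts for each element — a protein q, or a modified protein site
qdna — are scaled by the sample's total PSM count, log2-transformed
against the median of that element across all samples, and standardized
per sample (z-score), giving Zq at the protein level and, after
subtracting the protein's own profile, the protein-normalized site
quantity Zq_qdna that isolates site-specific changes from changes of
the whole protein.

The median-of-all-samples reference is deliberately conservative: an
element behaving like the cohort median scores R = 0 regardless of a
group effect confined to a minority of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
#: elements must exceed this summed PSM count across samples (strict)
DEFAULT_MIN_TOTAL = 15


@dataclass
class QuantMatrix:
    """Elements x samples quantitation with all intermediate layers.

    X: raw counts; F: depth-scaled fractions; R: log2 vs the per-element
    median across samples; Z: per-sample z-scores of R.
    """

    X: pd.DataFrame
    F: pd.DataFrame
    R: pd.DataFrame
    Z: pd.DataFrame
    totals: pd.Series  # per-sample scaling totals
    pseudocount: float

    @property
    def samples(self) -> list[str]:
        return list(self.X.columns)

    @property
    def elements(self) -> list:
        return list(self.X.index)


def quantify(
    counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    totals: pd.Series | None = None,
) -> QuantMatrix:
    """Standardized spectral-count quantitation of a count table.

    ``counts``: elements x samples non-negative integers.  ``totals``
    optionally supplies the per-sample total PSM counts used for depth
    scaling (e.g. the whole experiment's totals when quantifying a
    subset of elements); defaults to the column sums of ``counts``.
    """
    X = counts.astype(float)
    if (X.values < 0).any():
        raise ValueError("counts must be non-negative")
    if totals is None:
        totals = X.sum(axis=0)
    totals = totals.astype(float).reindex(X.columns)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total PSMs in samples {bad}")
    F = (X + pseudocount).div(totals, axis=1)
    R = np.log2(F.div(F.median(axis=1), axis=0))
    mu = R.mean(axis=0)
    sd = R.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero variance across elements in samples {bad}")
    Z = (R - mu).div(sd, axis=1)
    return QuantMatrix(X=X, F=F, R=R, Z=Z, totals=totals, pseudocount=pseudocount)


def filter_quantifiable(
    counts: pd.DataFrame,
    min_total: int = DEFAULT_MIN_TOTAL,
    require_all_samples: bool = True,
) -> pd.DataFrame:
    """Reliable-element filter: summed PSMs strictly above ``min_total``
    and, optionally, at least one PSM in every sample."""
    keep = counts.sum(axis=1) > min_total
    if require_all_samples:
        keep &= (counts >= 1).all(axis=1)
    return counts.loc[keep]


def protein_normalize(
    site_matrix: QuantMatrix,
    protein_matrix: QuantMatrix,
    site_protein: pd.Series,
) -> pd.DataFrame:
    """Protein-normalized site quantitation Zq_qdna.

    The site's log2 ratio is corrected by its protein's log2 ratio —
    R_site(e, s) - R_protein(q(e), s) — and the corrected values are
    standardized per sample.  Subtraction happens on the log2-ratio
    scale, where site and protein are commensurable; subtracting the
    z-score layers instead would mix spreads computed over different
    element populations and can amplify a mild protein trend into a
    spurious correction.  Sites whose protein is absent from the
    protein matrix (e.g. failed the reliability filter) are dropped
    with a log message.
    """
    if list(site_matrix.samples) != list(protein_matrix.samples):
        raise ValueError("site and protein matrices must share samples")
    have = site_protein.isin(protein_matrix.R.index)
    dropped = list(site_protein.index[~have])
    if dropped:
        logger.warning(
            "%d sites dropped: protein not quantified (%s%s)",
            len(dropped), ", ".join(map(str, dropped[:5])), "..." if len(dropped) > 5 else "",
        )
    kept = site_protein.index[have]
    rs = site_matrix.R.loc[kept]
    rp = protein_matrix.R.loc[site_protein.loc[kept].values].to_numpy()
    diff = pd.DataFrame(rs.to_numpy() - rp, index=kept, columns=site_matrix.samples)
    mu = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero variance after protein normalization")
    return (diff - mu).div(sd, axis=1)
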