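"""Biomarker discovery: frequency filter, rank-sum screen, FDR, DE.

Candidate peptides must be detected in at least 70% of cases or 70% of
controls (detection = non-zero normalized amplitude); the case-control
amplitude difference of each candidate is screened with the two-sided
Wilcoxon rank-sum test (zeros enter as ties at the bottom of the
ranking), p-values are corrected by the Benjamini-Hochberg step-up
procedure, and peptides with adjusted p below the significance level
form the biomarker panel.  The panel also reports each peptide's
differential excretion (DE): the signed ratio of (mean amplitude x
detection frequency) between the groups, with means taken over all
samples counting undetected values as 0, and the negative reciprocal
when controls exceed cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BiomarkerPanel",
    "detection_frequency",
    "wilcoxon_screen",
    "bh_adjust",
    "differential_excretion",
    "select_panel",
    "discover_panel",
]

#: combined sample size up to which the exact rank-sum null is used
#: (kept small enough to verify against full enumeration)
EXACT_MAX_N = 25


def _groups(matrix: pd.DataFrame, labels: pd.Series
            ) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        missing = matrix.index[labels.isna()].tolist()
        raise ValueError(f"labels missing for samples {missing[:5]}")
    case = labels.astype(bool).to_numpy()
    if case.all() or not case.any():
        raise ValueError("both case and control groups must be non-empty")
    return case, ~case


def detection_frequency(matrix: pd.DataFrame,
                        labels: pd.Series) -> pd.DataFrame:
    """Per-peptide detection frequency (amplitude > 0) in each group."""
    case, ctrl = _groups(matrix, labels)
    detected = matrix.to_numpy() > 0
    return pd.DataFrame(
        {
            "freq_case": detected[case].mean(axis=0),
            "freq_control": detected[ctrl].mean(axis=0),
        },
        index=matrix.columns,
    )


def wilcoxon_screen(matrix: pd.DataFrame, labels: pd.Series,
                    exact_max_n: int = EXACT_MAX_N) -> pd.DataFrame:
    """Two-sided rank-sum p-value per peptide.

    Undetected samples enter as amplitude 0 and tie at the bottom of
    the ranking (mid-ranks).  The exact permutation null is used when
    the combined sample size is at most ``exact_max_n`` and the column
    has no ties; otherwise the normal approximation with tie correction
    and continuity correction.  Constant columns are degenerate: p is
    set to 1 and flagged.
    """
    case, ctrl = _groups(matrix, labels)
    values = matrix.to_numpy()
    n = values.shape[0]
    p = np.ones(matrix.shape[1])
    degenerate = np.zeros(matrix.shape[1], dtype=bool)
    for j in range(matrix.shape[1]):
        col = values[:, j]
        x, y = col[case], col[ctrl]
        if np.all(col == col[0]):
            degenerate[j] = True
            continue
        has_ties = np.unique(col).size < n
        method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
        p[j] = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue
    return pd.DataFrame({"p_raw": p, "degenerate": degenerate},
                        index=matrix.columns)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_excretion(matrix: pd.DataFrame, labels: pd.Series,
                           peptide_id: str) -> tuple[float, bool]:
    """Signed differential-excretion ratio of one peptide.

    Each group's product is (mean amplitude over *all* its samples,
    counting undetected as 0) x (detection frequency).  DE is the
    case/control product ratio when cases excrete more, the negative
    control/case ratio when controls excrete more, and +1.0 on exact
    equality.  Returns ``(de, undefined)``; ``undefined`` is True (and
    DE is NaN) when either product is 0.
    """
    if peptide_id not in matrix.columns:
        raise KeyError(f"peptide {peptide_id!r} not in matrix")
    case, ctrl = _groups(matrix, labels)
    col = matrix[peptide_id].to_numpy()
    prod_case = col[case].mean() * (col[case] > 0).mean()
    prod_ctrl = col[ctrl].mean() * (col[ctrl] > 0).mean()
    if prod_case == 0 or prod_ctrl == 0:
        return float("nan"), True
    if prod_case > prod_ctrl:
        return float(prod_case / prod_ctrl), False
    if prod_case < prod_ctrl:
        return float(-prod_ctrl / prod_case), False
    return 1.0, False


@dataclass
class BiomarkerPanel:
    """Selected differential peptides with their screening statistics."""

    records: pd.DataFrame      # per-candidate statistics (all tested)
    selected: pd.DataFrame     # rows passing the filters, p_adj ascending
    freq_min: float
    alpha: float
    use_adjusted: bool = True

    @property
    def peptide_ids(self) -> list[str]:
        return self.selected.index.tolist()

    def __len__(self) -> int:
        return len(self.selected)


def select_panel(records: pd.DataFrame, freq_min: float = 0.70,
                 alpha: float = 0.05,
                 use_adjusted: bool = True) -> BiomarkerPanel:
    """Apply the frequency and significance filters to screened records.

    Keeps peptides whose detection frequency reaches ``freq_min`` in at
    least one group (boundary inclusive) and whose adjusted p-value is
    strictly below ``alpha`` (raw p when ``use_adjusted`` is False);
    the result is sorted by adjusted p, ties by peptide id.
    """
    pcol = "p_adj" if use_adjusted else "p_raw"
    passing = records[
        (records[["freq_case", "freq_control"]].max(axis=1) >= freq_min)
        & (records[pcol] < alpha)
    ]
    passing = passing.iloc[np.lexsort((passing.index.to_numpy(),
                                       passing[pcol].to_numpy()))]
    return BiomarkerPanel(records=records, selected=passing,
                          freq_min=freq_min, alpha=alpha,
                          use_adjusted=use_adjusted)


def discover_panel(matrix: pd.DataFrame, labels: pd.Series,
                   freq_min: float = 0.70, alpha: float = 0.05,
                   candidate_ids=None,
                   use_adjusted: bool = True) -> BiomarkerPanel:
    """Full discovery stage on one amplitude matrix.

    The frequency filter is applied first and only frequency-passing
    candidates enter the rank-sum screen and the multiple-testing
    correction, so the correction is over the peptides actually tested.
    ``candidate_ids`` restricts candidacy (the pipeline excludes the
    housekeeping normalizer peptides here, since their post-
    normalization amplitudes are anchored by construction).
    """
    sub = matrix if candidate_ids is None else matrix[list(candidate_ids)]
    freq = detection_frequency(sub, labels)
    eligible = freq[freq.max(axis=1) >= freq_min].index
    tested = sub[list(eligible)]
    if len(eligible):
        screen = wilcoxon_screen(tested, labels)
        p_adj = bh_adjust(screen["p_raw"].to_numpy())
    else:
        screen = pd.DataFrame(columns=["p_raw", "degenerate"], index=eligible)
        p_adj = np.empty(0)
    de = [differential_excretion(sub, labels, pid) for pid in eligible]
    records = pd.DataFrame(
        {
            "freq_case": freq.loc[eligible, "freq_case"],
            "freq_control": freq.loc[eligible, "freq_control"],
            "p_raw": screen["p_raw"],
            "p_adj": p_adj,
            "degenerate": screen["degenerate"],
            "differential_excretion": [d[0] for d in de],
            "de_undefined": [d[1] for d in de],
        },
        index=eligible,
    )
    records.index.name = "peptide_id"
    return select_panel(records, freq_min=freq_min, alpha=alpha,
                        use_adjusted=use_adjusted)
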