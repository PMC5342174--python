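"""CE-MS peak-list processing: calibration, normalization, clustering.

One urine sample yields one deconvoluted peak list (mass in Da, CE
migration time in minutes, signal amplitude).  Three steps turn a set
of such profiles into a catalogue-aligned amplitude matrix:

1. migration-time calibration against reference peptides by locally
   weighted regression (electrophoretic drift varies between runs);
2. amplitude normalization against housekeeping peptides with stable
   excretion, cancelling urine dilution and analytical variance;
3. clustering of detections onto catalogue peptides with a <50 ppm mass
   tolerance and a migration-time window that widens linearly from 2%
   at 19 min to 5% at 45 min (analyte diffusion broadens late peaks).

The matrix encodes "not detected" as 0, matching the convention of the
downstream frequency filters and differential-excretion statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from acspredict.errors import CalibrationError, NormalizationError

__all__ = [
    "RawProfile",
    "cluster_width",
    "cluster_half_window",
    "calibrate_migration_time",
    "normalize_amplitudes",
    "match_to_catalog",
]

#: electropherogram span (min) over which the cluster width ramps up
_T_LO, _T_HI = 19.0, 45.0
_W_LO, _W_HI = 0.02, 0.05


@dataclass
class RawProfile:
    """One sample's deconvoluted CE-MS peak list."""

    sample_id: str
    mass_da: np.ndarray
    cemt_min: np.ndarray
    amplitude: np.ndarray
    #: processing annotations (calibration residual, warnings, ...)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mass_da = np.asarray(self.mass_da, dtype=float)
        self.cemt_min = np.asarray(self.cemt_min, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        n = self.mass_da.size
        if self.cemt_min.size != n or self.amplitude.size != n:
            raise ValueError("detection arrays must have equal length")
        if n and (np.any(self.mass_da <= 0) or np.any(self.amplitude < 0)):
            raise ValueError("masses must be positive, amplitudes >= 0")
        if n and (np.any(self.cemt_min < 0) or np.any(self.cemt_min > 60)):
            raise ValueError("migration times must lie in [0, 60] min")

    def __len__(self) -> int:
        return self.mass_da.size

    def replace(self, **kw) -> "RawProfile":
        data = {
            "sample_id": self.sample_id,
            "mass_da": self.mass_da,
            "cemt_min": self.cemt_min,
            "amplitude": self.amplitude,
            "flags": dict(self.flags),
        }
        data.update(kw)
        return RawProfile(**data)


def cluster_width(cemt_min):
    """Relative migration-time cluster width at time ``t``.

    Ramps linearly from 2% at 19 min to 5% at 45 min and is clamped to
    those endpoints outside the electropherogram; the value is the full
    relative window, i.e. a detection matches a catalogue peptide at
    time ``t_p`` when ``|t - t_p| <= cluster_width(t_p) * t_p / 2``.
    """
    t = np.clip(np.asarray(cemt_min, dtype=float), _T_LO, _T_HI)
    w = _W_LO + (_W_HI - _W_LO) * (t - _T_LO) / (_T_HI - _T_LO)
    return w if w.ndim else float(w)


def cluster_half_window(cemt_min):
    """Absolute half-window (minutes) of the cluster rule at ``t``."""
    t = np.asarray(cemt_min, dtype=float)
    w = np.clip(t, _T_LO, _T_HI)
    w = _W_LO + (_W_HI - _W_LO) * (w - _T_LO) / (_T_HI - _T_LO)
    out = w * t / 2.0
    return out if out.ndim else float(out)


def _match_anchors(profile: RawProfile, reference: pd.DataFrame,
                   mass_tol_ppm: float, time_window_min: float,
                   mutual: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Pair reference peptides with profile detections.

    For each reference peptide, the detection with the smallest ppm
    deviation among those within ``mass_tol_ppm`` (strict) and
    ``time_window_min`` is taken.  With ``mutual`` (default), a pair is
    kept only when the detection's nearest eligible reference is that
    same peptide, which discards pairings of a detection with a close
    neighbour of its true peptide.  Returns (reference rows, detection
    indices); reference peptides without an eligible detection are
    omitted.
    """
    ref_mass = reference["mass_da"].to_numpy()
    ref_time = reference["cemt_min"].to_numpy()
    order = np.argsort(profile.mass_da, kind="stable")
    sm = profile.mass_da[order]

    def best_detection(r: int) -> int:
        m, t = ref_mass[r], ref_time[r]
        tol = m * mass_tol_ppm * 1e-6
        lo = np.searchsorted(sm, m - tol, side="right")
        hi = np.searchsorted(sm, m + tol, side="left")
        cand = order[lo:hi]
        cand = cand[np.abs(profile.cemt_min[cand] - t) <= time_window_min]
        if cand.size == 0:
            return -1
        ppm = np.abs(profile.mass_da[cand] - m) / m
        return int(cand[np.argmin(ppm)])

    ref_order = np.argsort(ref_mass, kind="stable")
    srm = ref_mass[ref_order]

    def best_reference(d: int) -> int:
        m, t = profile.mass_da[d], profile.cemt_min[d]
        lo = np.searchsorted(srm, m / (1 + mass_tol_ppm * 1e-6), side="left")
        hi = np.searchsorted(srm, m / (1 - mass_tol_ppm * 1e-6), side="right")
        cand = ref_order[lo:hi]
        ok = (np.abs(m - ref_mass[cand]) / ref_mass[cand] < mass_tol_ppm * 1e-6) \
            & (np.abs(t - ref_time[cand]) <= time_window_min)
        cand = cand[ok]
        if cand.size == 0:
            return -1
        ppm = np.abs(m - ref_mass[cand]) / ref_mass[cand]
        return int(cand[np.argmin(ppm)])

    ref_rows, det_idx = [], []
    for r in range(len(reference)):
        d = best_detection(r)
        if d < 0:
            continue
        if mutual and best_reference(d) != r:
            continue
        ref_rows.append(r)
        det_idx.append(d)
    return np.asarray(ref_rows, dtype=int), np.asarray(det_idx, dtype=int)


def calibrate_migration_time(profile: RawProfile, reference: pd.DataFrame,
                             span: float = 0.3, *,
                             mass_tol_ppm: float = 50.0,
                             anchor_time_window_min: float = 2.0,
                             max_residual_min: float = 0.35,
                             min_anchors: int = 10) -> RawProfile:
    """Map observed migration times onto the reference time scale.

    Anchor pairs (observed time, reference time) are found by mass
    within ``mass_tol_ppm`` and time within a coarse pre-calibration
    window; a locally weighted linear regression (tricube weights, one
    robustness iteration, ``span`` of the anchors per fit) of reference
    on observed time is fitted on the anchors and applied to every
    detection by interpolation (linear extrapolation beyond the anchor
    range).  The maximum absolute anchor residual is stored in
    ``flags["calibration_max_residual_min"]``; residuals above
    ``max_residual_min`` set ``flags["calibration_warning"]`` instead of
    being silently accepted.
    """
    ref_rows, det_idx = _match_anchors(profile, reference, mass_tol_ppm,
                                       anchor_time_window_min)
    if det_idx.size < min_anchors:
        raise CalibrationError(
            int(det_idx.size),
            f"only {det_idx.size} reference anchors matched in profile "
            f"{profile.sample_id!r}; need at least {min_anchors}")
    x = profile.cemt_min[det_idx]
    y = reference["cemt_min"].to_numpy()[ref_rows]

    # robust anchor rejection: a mis-paired anchor (its true peptide
    # undetected, a mass neighbour within tolerance) deviates far more
    # than instrumental jitter and would contaminate both the fit and
    # the residual report
    resid0 = y - x
    med = np.median(resid0)
    mad = np.median(np.abs(resid0 - med))
    if mad > 0:
        keep = np.abs(resid0 - med) <= 3.5 * 1.4826 * mad
        if keep.sum() >= min_anchors:
            x, y = x[keep], y[keep]
            det_idx = det_idx[keep]

    fit = lowess(y, x, frac=span, it=1, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    # collapse duplicate abscissae so interpolation is well defined
    xs, inv = np.unique(xs, return_index=True)
    ys = ys[inv]
    if xs.size < 2:
        raise CalibrationError(int(det_idx.size),
                               "anchors collapse to a single time point")

    def apply(t: np.ndarray) -> np.ndarray:
        out = np.interp(t, xs, ys)
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        below = t < xs[0]
        above = t > xs[-1]
        out = np.where(below, ys[0] + (t - xs[0]) * lo_slope, out)
        out = np.where(above, ys[-1] + (t - xs[-1]) * hi_slope, out)
        return out

    new_times = apply(profile.cemt_min)
    residual = float(np.max(np.abs(apply(x) - y)))
    flags = dict(profile.flags)
    flags["calibration_max_residual_min"] = residual
    flags["calibration_n_anchors"] = int(det_idx.size)
    if residual > max_residual_min:
        flags["calibration_warning"] = True
    out = profile.replace(cemt_min=np.clip(new_times, 0.0, 60.0))
    out.flags = flags
    return out


def normalize_amplitudes(profile: RawProfile, reference: pd.DataFrame,
                         method: str = "regression", *,
                         mass_tol_ppm: float = 50.0,
                         min_housekeeping: int = 3) -> RawProfile:
    """Divide all amplitudes by the housekeeping-derived scale factor.

    The factor is the slope of the no-intercept linear regression of
    observed housekeeping amplitudes on their catalogue reference
    amplitudes (``method="regression"``, the default) or the median of
    the observed/reference ratios (``method="median_ratio"``).
    Housekeeping detections are located with the same mass tolerance
    and the cluster-width time window used for matching.
    """
    hk = reference[reference["is_housekeeping"]]
    if hk.empty:
        raise NormalizationError("reference catalogue has no housekeeping "
                                 "peptides")
    if "ref_amplitude" not in hk.columns:
        raise NormalizationError("reference catalogue lacks housekeeping "
                                 "reference amplitudes")
    windows = cluster_half_window(hk["cemt_min"].to_numpy())
    # per-peptide time windows: reuse the anchor matcher with the widest
    # window, then re-check each pair against its own cluster window
    rows, det = _match_anchors(profile, hk, mass_tol_ppm,
                               float(np.max(windows)) if len(hk) else 0.0)
    if rows.size:
        keep = (np.abs(profile.cemt_min[det]
                       - hk["cemt_min"].to_numpy()[rows]) <= windows[rows])
        rows, det = rows[keep], det[keep]
    if rows.size < min_housekeeping:
        raise NormalizationError(
            f"only {rows.size} housekeeping peptides detected in profile "
            f"{profile.sample_id!r}; need at least {min_housekeeping}")
    obs = profile.amplitude[det]
    ref = hk["ref_amplitude"].to_numpy()[rows]
    if method == "regression":
        scale = float(np.dot(ref, obs) / np.dot(ref, ref))
    elif method == "median_ratio":
        scale = float(np.median(obs / ref))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if scale <= 0:
        raise NormalizationError(
            f"non-positive normalization factor {scale!r} for profile "
            f"{profile.sample_id!r}")
    out = profile.replace(amplitude=profile.amplitude / scale)
    out.flags["normalization_factor"] = scale
    out.flags["normalization_n_housekeeping"] = int(rows.size)
    return out


def match_to_catalog(profiles: list[RawProfile], reference: pd.DataFrame,
                     mass_tol_ppm: float = 50.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster detections onto catalogue peptides.

    A detection is assigned to catalogue peptide ``p`` iff its mass
    deviation is strictly below ``mass_tol_ppm`` and its migration time
    lies within the cluster window of ``p``; among multiple eligible
    peptides the smallest ppm deviation wins, ties broken by smaller
    time deviation and then lexicographically smaller peptide id.
    Multiple detections of one peptide within a sample are summed.

    Returns ``(matrix, report)``: the sample x peptide amplitude matrix
    (0 = undetected) and a per-sample report with detection, matched and
    unmatched counts plus a warning flag for empty profiles.
    """
    ref_mass = reference["mass_da"].to_numpy()
    ref_time = reference["cemt_min"].to_numpy()
    half_win = cluster_half_window(ref_time)
    # rank of each peptide id in lexicographic order, for tie-breaking
    id_rank = np.argsort(np.argsort(reference.index.to_numpy()))
    order = np.argsort(ref_mass, kind="stable")
    sorted_mass = ref_mass[order]

    matrix = np.zeros((len(profiles), len(reference)))
    report_rows = []
    for i, prof in enumerate(profiles):
        n = len(prof)
        if n == 0:
            report_rows.append({"sample_id": prof.sample_id, "detections": 0,
                                "matched": 0, "unmatched": 0,
                                "empty_profile": True})
            continue
        m = prof.mass_da
        lo = np.searchsorted(sorted_mass, m / (1 + mass_tol_ppm * 1e-6),
                             side="left")
        hi = np.searchsorted(sorted_mass, m / (1 - mass_tol_ppm * 1e-6),
                             side="right")
        counts = hi - lo
        det_of_pair = np.repeat(np.arange(n), counts)
        if det_of_pair.size:
            offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
            pair_pos = np.arange(det_of_pair.size) - offsets[det_of_pair]
            cand = order[lo[det_of_pair] + pair_pos]
        else:
            cand = np.empty(0, dtype=int)

        dm = np.abs(m[det_of_pair] - ref_mass[cand])
        ppm = dm / ref_mass[cand] * 1e6
        dt = np.abs(prof.cemt_min[det_of_pair] - ref_time[cand])
        ok = (ppm < mass_tol_ppm) & (dt <= half_win[cand])
        det_of_pair, cand, ppm, dt = (det_of_pair[ok], cand[ok],
                                      ppm[ok], dt[ok])
        matched = 0
        if det_of_pair.size:
            # best candidate per detection: (ppm, |dt|, id rank) ascending
            sel = np.lexsort((id_rank[cand], dt, ppm, det_of_pair))
            det_sorted = det_of_pair[sel]
            first = np.ones(det_sorted.size, dtype=bool)
            first[1:] = det_sorted[1:] != det_sorted[:-1]
            winners_det = det_sorted[first]
            winners_pep = cand[sel][first]
            np.add.at(matrix[i], winners_pep, prof.amplitude[winners_det])
            matched = int(winners_det.size)
        report_rows.append({"sample_id": prof.sample_id, "detections": n,
                            "matched": matched, "unmatched": n - matched,
                            "empty_profile": False})

    index = pd.Index([p.sample_id for p in profiles], name="sample_id")
    out = pd.DataFrame(matrix, index=index, columns=reference.index)
    report = pd.DataFrame(report_rows).set_index("sample_id")
    return out, report
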