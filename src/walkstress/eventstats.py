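"""Stimulus-anchored window statistics.

For every self-report, a matched pair of feature means is formed: the
nonstimuli window [t0 - L, t0) before the subject passes the reported
location and the stimuli window [t0, t0 + L) after it, with L swept from
5 to 240 s. Pairs feed a random-intercept linear mixed-effects model
(y_ij = mu + beta * x_ij + u_i + e_ij, subject as random effect) and
per-stimulus-type Welch two-sample t-tests at alpha = 0.05. No
multiple-testing correction is applied; the full grid of raw p-values is
kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import FeatureSeries
from .io_formats import GeoTrack, StimulusReport
from .preprocess import IntervalSet

__all__ = [
    "WindowPair",
    "LmeResult",
    "TTestResult",
    "passage_time",
    "extract_window_pair",
    "build_pair_table",
    "fit_lme",
    "ttest_by_type",
    "sweep_window_lengths",
    "simulate_pair_table",
    "WINDOW_LENGTHS_S",
]

WINDOW_LENGTHS_S = range(5, 241)
ALPHA = 0.05
#: Reports farther than this from the walked route are excluded.
MAX_REPORT_ROUTE_DIST_M = 40.0
#: Minimum fraction of a window that must be valid (inside the trip and
#: outside interruptions).
MIN_WINDOW_COVERAGE = 0.5


@dataclass(frozen=True)
class WindowPair:
    """Matched pre/post-passage feature means for one report."""

    trip_id: str
    subject_id: str
    stimulus_types: tuple[int, ...]
    window_length_s: float
    t0_s: float
    nonstimuli_value: float
    stimuli_value: float


@dataclass(frozen=True)
class LmeResult:
    """Random-intercept LME fit summary for one feature and window length."""

    feature: str
    window_length_s: float
    beta: float
    beta_se: float
    p_value: float
    mu: float
    subject_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    pooled_fallback: bool = False


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t-test for one stimulus type / feature / length."""

    stimulus_type: int
    feature: str
    window_length_s: float
    t_stat: float
    p_value: float
    n_nonstimuli: int
    n_stimuli: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def passage_time(track: GeoTrack, position: tuple[float, float]) -> tuple[float, float]:
    """Time of the track fix nearest the reported position, plus distance."""
    d = np.hypot(track.positions[:, 0] - position[0], track.positions[:, 1] - position[1])
    i = int(np.argmin(d))
    return float(track.timestamps[i]), float(d[i])


def _window_mean(
    series: FeatureSeries, a: float, b: float, interruptions: IntervalSet
) -> float:
    t = series.timestamps
    lo, hi = np.searchsorted(t, [a, b])
    tv = t[lo:hi]
    vv = series.values[lo:hi]
    keep = ~interruptions.contains(tv)
    if not np.any(keep):
        return float("nan")
    return float(np.mean(vv[keep]))


def extract_window_pair(
    track: GeoTrack,
    trip_duration_s: float,
    report: StimulusReport,
    series: FeatureSeries,
    window_length_s: float,
    interruptions: IntervalSet = IntervalSet(),
    subject_id: str = "",
    other_t0s: np.ndarray | None = None,
) -> WindowPair | str:
    """Build the (nonstimuli, stimuli) mean pair for one report.

    Returns an exclusion-reason string instead of a pair when the report is
    off route, a window is truncated by the trip boundary, the stimuli
    window overlaps an earlier report's stimuli window, or less than half
    of either window is valid.
    """
    L = window_length_s
    t0, dist = passage_time(track, report.position)
    if dist > MAX_REPORT_ROUTE_DIST_M:
        return "off_route"
    if t0 - L < 0 or t0 + L > trip_duration_s:
        return "truncated"
    if other_t0s is not None:
        earlier = other_t0s[other_t0s < t0]
        if np.any(earlier + L > t0):
            return "overlap"
    for a, b in ((t0 - L, t0), (t0, t0 + L)):
        if interruptions.overlap_s(a, b) > (1 - MIN_WINDOW_COVERAGE) * L:
            return "interrupted"
    non = _window_mean(series, t0 - L, t0, interruptions)
    stim = _window_mean(series, t0, t0 + L, interruptions)
    if np.isnan(non) or np.isnan(stim):
        return "no_samples"
    return WindowPair(
        trip_id=report.trip_id,
        subject_id=subject_id,
        stimulus_types=report.stimulus_types,
        window_length_s=L,
        t0_s=t0,
        nonstimuli_value=non,
        stimuli_value=stim,
    )


def build_pair_table(pairs: list[WindowPair]) -> pd.DataFrame:
    """Long-format table: one row per (pair, condition) with 0/1 indicator."""
    rows = []
    for p in pairs:
        for x, y in ((0, p.nonstimuli_value), (1, p.stimuli_value)):
            rows.append(
                {
                    "subject": p.subject_id,
                    "trip_id": p.trip_id,
                    "x": x,
                    "y": y,
                    "types": p.stimulus_types,
                    "t0_s": p.t0_s,
                }
            )
    return pd.DataFrame(rows)


def fit_lme(table: pd.DataFrame, feature: str = "", window_length_s: float = 0.0) -> LmeResult:
    """Fit y = mu + beta*x + u_subject + e by REML (Wald p-value for beta).

    Falls back to pooled OLS (flagged) if the mixed model cannot be fitted.
    Requires >= 2 subjects, >= 10 observations, and variation in x.
    """
    import statsmodels.api as sm

    if table["x"].nunique() < 2:
        raise ValueError("stimulus indicator x has no contrast")
    n_subj = table["subject"].nunique()
    if n_subj < 2 or len(table) < 10:
        raise ValueError("need >= 2 subjects and >= 10 observations")
    y = table["y"].to_numpy(float)
    X = sm.add_constant(table["x"].to_numpy(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=table["subject"].to_numpy())
            fit = model.fit(reml=True)
        beta = float(fit.params[1])
        p = float(fit.pvalues[1])
        return LmeResult(
            feature=feature,
            window_length_s=window_length_s,
            beta=beta,
            beta_se=float(fit.bse[1]),
            p_value=p,
            mu=float(fit.params[0]),
            subject_var=float(np.squeeze(fit.cov_re)),
            residual_var=float(fit.scale),
            n_obs=len(y),
            n_subjects=n_subj,
        )
    except (np.linalg.LinAlgError, ValueError):
        ols = sm.OLS(y, X).fit()
        return LmeResult(
            feature=feature,
            window_length_s=window_length_s,
            beta=float(ols.params[1]),
            beta_se=float(ols.bse[1]),
            p_value=float(ols.pvalues[1]),
            mu=float(ols.params[0]),
            subject_var=0.0,
            residual_var=float(ols.scale),
            n_obs=len(y),
            n_subjects=n_subj,
            pooled_fallback=True,
        )


def ttest_by_type(
    pairs: list[WindowPair], feature: str, window_length_s: float
) -> list[TTestResult]:
    """Welch two-sample t-test of stimuli vs nonstimuli means per type."""
    results = []
    for tid in range(1, 15):
        sel = [p for p in pairs if tid in p.stimulus_types]
        non = np.array([p.nonstimuli_value for p in sel])
        stim = np.array([p.stimuli_value for p in sel])
        if len(non) < 2 or len(stim) < 2:
            continue
        if np.array_equal(non, stim):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sstats.ttest_ind(stim, non, equal_var=False)
        results.append(
            TTestResult(
                stimulus_type=tid,
                feature=feature,
                window_length_s=window_length_s,
                t_stat=float(t_stat),
                p_value=float(p),
                n_nonstimuli=len(non),
                n_stimuli=len(stim),
            )
        )
    return results


def collect_pairs(
    trip_data: dict[str, dict],
    reports: list[StimulusReport],
    feature: str,
    window_length_s: float,
) -> list[WindowPair]:
    """Extract all retained window pairs of one feature at one length.

    ``trip_data`` maps trip_id to a dict with keys ``track``, ``duration_s``,
    ``subject_id``, ``interruptions`` and ``features`` (name -> series).
    Exclusion is order-independent: overlap resolution keeps the earlier-t0
    report.
    """
    by_trip: dict[str, list[StimulusReport]] = {}
    for r in reports:
        by_trip.setdefault(r.trip_id, []).append(r)
    pairs: list[WindowPair] = []
    for trip_id, reps in by_trip.items():
        td = trip_data.get(trip_id)
        if td is None or feature not in td["features"]:
            continue
        series = td["features"][feature]
        if len(series) == 0:
            continue
        t0s = np.array([passage_time(td["track"], r.position)[0] for r in reps])
        for i, r in enumerate(reps):
            others = np.delete(t0s, i)
            out = extract_window_pair(
                td["track"],
                td["duration_s"],
                r,
                series,
                window_length_s,
                td.get("interruptions", IntervalSet()),
                subject_id=td["subject_id"],
                other_t0s=others,
            )
            if isinstance(out, WindowPair):
                pairs.append(out)
    return pairs


def sweep_window_lengths(
    trip_data: dict[str, dict],
    reports: list[StimulusReport],
    features: list[str],
    lengths: list[int] | range = WINDOW_LENGTHS_S,
    run_ttests: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Sweep window lengths, fitting the LME (and t-tests) at each.

    Returns the LME grid, the t-test grid and the smallest length with
    LME p < 0.05 per feature (NaN when none is significant).
    """
    lme_rows, tt_rows = [], []
    minimal: dict[str, float] = {}
    for feature in features:
        min_sig = float("nan")
        for L in lengths:
            pairs = collect_pairs(trip_data, reports, feature, float(L))
            if len(pairs) < 5:
                continue
            table = build_pair_table(pairs)
            try:
                res = fit_lme(table, feature, float(L))
            except ValueError:
                continue
            lme_rows.append(
                {
                    "feature": feature,
                    "length_s": L,
                    "beta": res.beta,
                    "p_value": res.p_value,
                    "n_pairs": len(pairs),
                    "pooled_fallback": res.pooled_fallback,
                }
            )
            if np.isnan(min_sig) and res.p_value < ALPHA:
                min_sig = float(L)
            if run_ttests:
                for tt in ttest_by_type(pairs, feature, float(L)):
                    tt_rows.append(
                        {
                            "feature": feature,
                            "type": tt.stimulus_type,
                            "length_s": L,
                            "t_stat": tt.t_stat,
                            "p_value": tt.p_value,
                            "significant": tt.significant,
                        }
                    )
        minimal[feature] = min_sig
    return pd.DataFrame(lme_rows), pd.DataFrame(tt_rows), minimal


def simulate_pair_table(
    n_subjects: int,
    pairs_per_subject: int,
    beta: float,
    sigma_subject: float,
    sigma_resid: float,
    rng: np.random.Generator,
    mu: float = 0.0,
) -> pd.DataFrame:
    """Draw a long-format pair table straight from the LME generative model.

    Used for calibration (type-I error, coverage) independently of the
    signal pipeline.
    """
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, sigma_subject)
        for _ in range(pairs_per_subject):
            for x in (0, 1):
                rows.append(
                    {
                        "subject": f"S{i}",
                        "trip_id": f"S{i}",
                        "x": x,
                        "y": mu + beta * x + u + rng.normal(0, sigma_resid),
                        "types": (1,),
                        "t0_s": 0.0,
                    }
                )
    return pd.DataFrame(rows)
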