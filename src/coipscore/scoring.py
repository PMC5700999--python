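"""Two-stage interactor calling for differential co-immunoprecipitation.

Stage 1 builds a *training set*: every precipitated protein quantified at
least twice in each condition is tested (Welch's unequal-variance t-test on
log10 intensities, Benjamini–Hochberg correction across proteins) and labeled
a true interactor if it is significantly more abundant in precipitates from
stressed cells, otherwise a false interactor.

Stage 2 turns the training labels into an *empirical error probability* as a
function of stress-side abundance: training proteins are split into
equal-count bins of their median log10 stress intensity, each bin contributes
an anchor (median intensity, fraction of false labels), the anchor sequence is
made nonincreasing by antitonic pool-adjacent-violators, and a
monotonicity-preserving cubic Hermite interpolant (Fritsch–Carlson tangent
limiting) through the adjusted anchors yields a continuous curve.  Reading the
curve at a protein's stress intensity gives its p-score — the estimated
probability that it is a false interactor — and proteins with p-score at or
below the threshold (default 0.05) are called interactors.

Proteins never detected under stress keep a missing p-score and are never
called; proteins detected only under stress are excluded from training but are
scored like everything else.  This asymmetric treatment of missingness is the
point of the procedure: condition-dependent dropout carries signal that a
plain per-protein test discards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ParameterError
from .io_formats import QuantTable

TRUE_INTERACTOR = "true_interactor"
FALSE_INTERACTOR = "false_interactor"


@dataclass(frozen=True)
class DifferentialTestResult:
    protein_id: str
    mean_log_control: float
    mean_log_stress: float
    t_statistic: float
    p_value: float
    q_value: float
    n_control: int
    n_stress: int


@dataclass(frozen=True)
class TrainingEntry:
    protein_id: str
    label: str  # TRUE_INTERACTOR or FALSE_INTERACTOR
    stress_summary: float  # median log10 stress intensity


@dataclass(frozen=True)
class PScoreRecord:
    protein_id: str
    stress_summary: float  # log10, NaN when never detected under stress
    p_score: float  # NaN iff stress_summary is NaN
    called: bool
    in_training_set: bool
    label_if_trained: str | None


def summarize_stress_intensity(q: QuantTable, protein_id: str) -> float:
    """Median log10 intensity over non-missing stress runs; NaN if none."""
    values = q.values_for(protein_id, "stress")
    if values.size == 0:
        return float("nan")
    return float(np.median(np.log10(values)))


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's two-sided t-test of ``b`` vs ``a``; returns (t, p).

    t is signed so that positive t means mean(b) > mean(a).  Degenerate
    zero-variance-in-both-groups inputs use the documented convention:
    p = 1 when the means are equal, p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, b.mean() - a.mean()), 0.0
    res = stats.ttest_ind(b, a, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def build_training_set(
    q: QuantTable, fdr_alpha: float = 0.05
) -> tuple[list[TrainingEntry], list[DifferentialTestResult]]:
    """Label quantified-in-both-conditions proteins by differential testing.

    A protein enters the training set when it has >= 2 non-missing intensities
    in each condition.  Included proteins are Welch-tested on log10
    intensities; q <= ``fdr_alpha`` together with a higher stress mean labels
    a protein a true interactor, everything else a false interactor.
    """
    entries: list[tuple[str, np.ndarray, np.ndarray]] = []
    for pid in q.protein_ids:
        ctrl = q.values_for(pid, "control")
        strs = q.values_for(pid, "stress")
        if ctrl.size >= 2 and strs.size >= 2:
            entries.append((pid, np.log10(ctrl), np.log10(strs)))
    if len(entries) < 2:
        raise InsufficientDataError(
            f"only {len(entries)} proteins quantified >=2x in both conditions"
        )

    t_stats, p_vals = [], []
    for _, log_ctrl, log_strs in entries:
        t, p = welch_test(log_ctrl, log_strs)
        t_stats.append(t)
        p_vals.append(p)
    q_vals = benjamini_hochberg(p_vals)

    training: list[TrainingEntry] = []
    results: list[DifferentialTestResult] = []
    for (pid, log_ctrl, log_strs), t, p, qv in zip(entries, t_stats, p_vals, q_vals):
        mean_c = float(log_ctrl.mean())
        mean_s = float(log_strs.mean())
        significant_up = qv <= fdr_alpha and mean_s > mean_c
        label = TRUE_INTERACTOR if significant_up else FALSE_INTERACTOR
        training.append(
            TrainingEntry(protein_id=pid, label=label, stress_summary=float(np.median(log_strs)))
        )
        results.append(
            DifferentialTestResult(
                protein_id=pid,
                mean_log_control=mean_c,
                mean_log_stress=mean_s,
                t_statistic=float(t),
                p_value=float(p),
                q_value=float(qv),
                n_control=log_ctrl.size,
                n_stress=log_strs.size,
            )
        )
    return training, results


def bin_training_set(
    training: list[TrainingEntry], n_bins: int = 10
) -> list[tuple[float, float]]:
    """Equal-count bins over stress intensity -> (median intensity, error fraction) anchors.

    Ties in stress intensity are broken by protein id for determinism.  The
    error fraction of a bin is n_false / (n_false + n_true).
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if len(training) < n_bins:
        raise InsufficientDataError(
            f"training set of {len(training)} cannot fill {n_bins} bins"
        )
    ordered = sorted(training, key=lambda e: (e.stress_summary, e.protein_id))
    anchors = []
    for chunk in np.array_split(np.arange(len(ordered)), n_bins):
        members = [ordered[i] for i in chunk]
        x = float(np.median([m.stress_summary for m in members]))
        n_false = sum(m.label == FALSE_INTERACTOR for m in members)
        anchors.append((x, n_false / len(members)))
    anchors.sort(key=lambda a: a[0])
    return anchors


# --- monotone error-probability model ---------------------------------------


def antitonic_pava(y, weights=None) -> np.ndarray:
    """Best nonincreasing fit to ``y`` in weighted least squares (PAVA).

    Classic pool-adjacent-violators on the reversed problem: adjacent blocks
    whose means increase are merged into their weighted mean until the block
    means are nonincreasing.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # blocks as (mean, weight, count) with nonincreasing means maintained
    means: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        means.append(float(yi))
        wts.append(float(wi))
        counts.append(1)
        while len(means) > 1 and means[-2] < means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), counts.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wts.append(wt)
            counts.append(c1 + c2)
    out = np.empty_like(y)
    pos = 0
    for m, c in zip(means, counts):
        out[pos : pos + c] = m
        pos += c
    return out


def _fritsch_carlson_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tangents for a monotonicity-preserving cubic Hermite interpolant.

    Secant-average initialization followed by the Fritsch–Carlson limiter:
    flat secants force zero tangents at both ends of their interval, and any
    interval with (m_i/d)^2 + (m_{i+1}/d)^2 > 9 has both tangents scaled back
    onto the circle of radius 3, which is sufficient for monotonicity.
    """
    n = x.size
    if n == 1:
        return np.zeros(1)
    d = np.diff(y) / np.diff(x)
    m = np.empty(n)
    m[0] = d[0]
    m[-1] = d[-1]
    if n > 2:
        m[1:-1] = (d[:-1] + d[1:]) / 2.0
    # a tangent adjacent to a flat interval must vanish
    for i in range(n - 1):
        if d[i] == 0.0:
            m[i] = 0.0
            m[i + 1] = 0.0
    for i in range(n - 1):
        if d[i] == 0.0:
            continue
        a = m[i] / d[i]
        b = m[i + 1] / d[i]
        if a < 0.0:  # tangent opposing the secant: clip (cannot happen after
            m[i] = 0.0  # averaging same-sign secants, kept for safety)
            a = 0.0
        if b < 0.0:
            m[i + 1] = 0.0
            b = 0.0
        s = a * a + b * b
        if s > 9.0:
            tau = 3.0 / math.sqrt(s)
            m[i] = tau * a * d[i]
            m[i + 1] = tau * b * d[i]
    return m


@dataclass(frozen=True)
class ErrorModel:
    """Monotone nonincreasing map from log10 stress intensity to error probability.

    ``x`` holds strictly increasing anchor abscissae, ``e`` the antitonically
    adjusted error fractions, ``slopes`` the Fritsch–Carlson tangents.
    Evaluation interpolates with the cubic Hermite basis inside
    [x[0], x[-1]] and clamps to the boundary anchor values outside.
    """

    x: np.ndarray
    e: np.ndarray
    slopes: np.ndarray

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def __call__(self, xq) -> np.ndarray | float:
        scalar = np.isscalar(xq)
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        if self.x.size == 1:
            out = np.full(xq.shape, self.e[0])
            return float(out[0]) if scalar else out
        xc = np.clip(xq, self.x[0], self.x[-1])
        idx = np.clip(np.searchsorted(self.x, xc, side="right") - 1, 0, self.x.size - 2)
        h = self.x[idx + 1] - self.x[idx]
        t = (xc - self.x[idx]) / h
        t2 = t * t
        t3 = t2 * t
        h00 = 2 * t3 - 3 * t2 + 1
        h10 = t3 - 2 * t2 + t
        h01 = -2 * t3 + 3 * t2
        h11 = t3 - t2
        out = (
            h00 * self.e[idx]
            + h10 * h * self.slopes[idx]
            + h01 * self.e[idx + 1]
            + h11 * h * self.slopes[idx + 1]
        )
        return float(out[0]) if scalar else out


def fit_error_model(anchors) -> ErrorModel:
    """Fit the monotone error-probability curve through binned anchors.

    Anchors sharing an abscissa are merged by averaging their error fractions;
    the error fractions are then made nonincreasing by antitonic PAVA and
    interpolated by the Fritsch–Carlson monotone cubic Hermite scheme.
    """
    if len(anchors) == 0:
        raise InsufficientDataError("no anchors to fit")
    merged: dict[float, list[float]] = {}
    for x, e in anchors:
        merged.setdefault(float(x), []).append(float(e))
    xs = np.array(sorted(merged), dtype=float)
    es = np.array([float(np.mean(merged[x])) for x in xs], dtype=float)
    es = antitonic_pava(es)
    slopes = _fritsch_carlson_slopes(xs, es)
    return ErrorModel(x=xs, e=es, slopes=slopes)


def assign_pscores(
    model: ErrorModel,
    q: QuantTable,
    training: list[TrainingEntry],
    threshold: float = 0.05,
) -> list[PScoreRecord]:
    """Score every protein of the table with the fitted error model.

    Output row count equals input protein count: proteins never detected
    under stress keep NaN summaries/p-scores and are never called.
    """
    by_id = {t.protein_id: t for t in training}
    records = []
    for pid in q.protein_ids:
        s = summarize_stress_intensity(q, pid)
        if math.isnan(s):
            p_score = float("nan")
            called = False
        else:
            p_score = float(model(s))
            called = p_score <= threshold
        trained = by_id.get(pid)
        records.append(
            PScoreRecord(
                protein_id=pid,
                stress_summary=s,
                p_score=p_score,
                called=called,
                in_training_set=trained is not None,
                label_if_trained=trained.label if trained else None,
            )
        )
    return records


def call_interactors(records: list[PScoreRecord], threshold: float = 0.05) -> list[str]:
    """Ids with p-score <= threshold, ascending by p-score then id."""
    called = [r for r in records if not math.isnan(r.p_score) and r.p_score <= threshold]
    called.sort(key=lambda r: (r.p_score, r.protein_id))
    return [r.protein_id for r in called]


def score_quant_table(
    q: QuantTable,
    fdr_alpha: float = 0.05,
    n_bins: int = 10,
    threshold: float = 0.05,
) -> tuple[list[PScoreRecord], list[DifferentialTestResult], ErrorModel]:
    """Run the full two-stage scoring on one intensity table."""
    training, diff = build_training_set(q, fdr_alpha=fdr_alpha)
    anchors = bin_training_set(training, n_bins=n_bins)
    model = fit_error_model(anchors)
    records = assign_pscores(model, q, training, threshold=threshold)
    return records, diff, model


def records_frame(
    records: list[PScoreRecord], diff: list[DifferentialTestResult]
) -> pd.DataFrame:
    """Join p-score records with their differential-test rows into one table."""
    rec = pd.DataFrame([r.__dict__ for r in records])
    dif = pd.DataFrame([d.__dict__ for d in diff])
    if dif.empty:
        return rec
    return rec.merge(dif, on="protein_id", how="left")
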