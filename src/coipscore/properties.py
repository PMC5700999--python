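"""Sequence-property characterization of an interactor set versus a proteome.

Raw properties are composition-only statistics: the mean of an amino-acid
property index over the standard residues of a sequence.  Because the mean of
a short sequence is noisy and composition-biased, raw values are normalized
against a Monte-Carlo null: 5000 random sequences of the same length drawn
i.i.d. from the background proteome's residue frequencies give a mean mu and
standard deviation sigma per scale, and z = (raw - mu) / sigma is reported.
Isoelectric points come from a Henderson–Hasselbalch charge model with the
IPC protein pKa set, solved by bisection.  Group distributions are visualized
by Gaussian-kernel density estimates and compared by Welch's unequal-variance
t-test (log space for strictly positive quantities such as pI and length, raw
scale for z-scores, which can be negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import scales as _scales
from .errors import DomainError, InsufficientDataError, ParameterError
from .scales import AA_INDEX, AA_ORDER, PropertyScale


def strip_transit_peptides(
    proteome: Mapping[str, str],
    cleavage: Mapping[str, tuple[float, int]],
    score_threshold: float,
) -> dict[str, str]:
    """Build a predicted mature proteome from targeting scores and cleavage sites.

    Keeps proteins whose targeting score exceeds ``score_threshold`` and cuts
    each retained sequence after the 1-based cleavage position (position 0
    keeps the full sequence).  Records whose cleavage site would leave an
    empty mature sequence are skipped.
    """
    mature: dict[str, str] = {}
    for pid, (score, pos) in cleavage.items():
        if pid not in proteome or score <= score_threshold:
            continue
        seq = proteome[pid]
        if pos >= len(seq):
            continue  # empty mature sequence is invalid; skip the record
        mature[pid] = seq[pos:]
    return mature


def aa_frequencies(proteome: Mapping[str, str]) -> np.ndarray:
    """Residue frequencies over the 20 standard amino acids, pooled over all sequences.

    Non-standard residues are excluded from numerator and denominator.
    Returned in :data:`scales.AA_ORDER` order, summing to 1.
    """
    counts = np.zeros(20, dtype=float)
    for seq in proteome.values():
        for aa in seq:
            idx = AA_INDEX.get(aa)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise DomainError("proteome contains no standard residues")
    return counts / total


def _standard_indices(seq: str) -> np.ndarray:
    return np.array([AA_INDEX[aa] for aa in seq if aa in AA_INDEX], dtype=np.intp)


def raw_property(seq: str, scale: PropertyScale) -> float:
    """Mean of the scale value over the standard residues of ``seq``."""
    idx = _standard_indices(seq)
    if idx.size == 0:
        raise DomainError(f"sequence has no standard residues for scale {scale.name!r}")
    return float(scale.vector[idx].mean())


@dataclass(frozen=True)
class NullDistribution:
    """Monte-Carlo null of a raw property for random sequences of one length."""

    scale_name: str
    sequence_length: int
    n_samples: int
    mu: float
    sigma: float
    source_frequencies: np.ndarray
    seed: int | None

    @property
    def valid(self) -> bool:
        return self.sigma > 0.0


def _draw_index_matrix(
    freqs: np.ndarray, length: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (20,) or np.any(freqs < 0) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
        raise ParameterError("frequencies must be a 20-vector summing to 1")
    if length < 1:
        raise ParameterError("sequence length must be >= 1")
    return rng.choice(20, size=(n, length), p=freqs / freqs.sum())


def _snap_sigma(draws: np.ndarray) -> float:
    """Sample sd with rounding noise snapped to an exact 0 for degenerate draws."""
    sigma = float(draws.std(ddof=1))
    if sigma <= 1e-12 * max(1.0, abs(float(draws.mean()))):
        return 0.0
    return sigma


def build_null(
    scale: PropertyScale,
    freqs: np.ndarray,
    length: int,
    n: int = 5000,
    seed: int | None = None,
) -> NullDistribution:
    """Monte-Carlo mu/sigma of ``raw_property`` over ``n`` random sequences."""
    rng = np.random.default_rng(seed)
    idx = _draw_index_matrix(freqs, length, n, rng)
    draws = scale.vector[idx].mean(axis=1)
    return NullDistribution(
        scale_name=scale.name,
        sequence_length=length,
        n_samples=n,
        mu=float(draws.mean()),
        sigma=_snap_sigma(draws),
        source_frequencies=np.asarray(freqs, dtype=float),
        seed=seed,
    )


def build_null_panel(
    scale_set: Mapping[str, PropertyScale],
    freqs: np.ndarray,
    length: int,
    n: int = 5000,
    seed: int | None = None,
) -> dict[str, NullDistribution]:
    """Nulls for several scales from one shared set of random sequences.

    The same 5000 random sequences serve every scale; per-scale mu and sigma
    are statistically identical to independent draws but cost one sampling
    pass, which keeps per-length nulls affordable for whole proteomes.
    """
    rng = np.random.default_rng(seed)
    idx = _draw_index_matrix(freqs, length, n, rng)
    panel = {}
    for name, scale in scale_set.items():
        draws = scale.vector[idx].mean(axis=1)
        panel[name] = NullDistribution(
            scale_name=name,
            sequence_length=length,
            n_samples=n,
            mu=float(draws.mean()),
            sigma=_snap_sigma(draws),
            source_frequencies=np.asarray(freqs, dtype=float),
            seed=seed,
        )
    return panel


def normalize_property(raw: float, null: NullDistribution) -> float:
    """z = (raw - mu) / sigma against the matched Monte-Carlo null."""
    if not null.valid:
        raise DomainError(
            f"null for {null.scale_name!r} at length {null.sequence_length} is degenerate (sigma = 0)"
        )
    return (raw - null.mu) / null.sigma


# --- isoelectric point -------------------------------------------------------


def net_charge(seq: str, ph: float) -> float:
    """Modeled net charge at ``ph``: termini plus D, E, C, Y, H, K, R side chains."""
    charge = 1.0 / (1.0 + 10.0 ** (ph - _scales.PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (_scales.PKA_CTERM - ph))
    for aa, pka in _scales.PKA_BASIC.items():
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in _scales.PKA_ACIDIC.items():
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-6) -> float:
    """pH of zero modeled net charge, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique.  Bisection
    runs until the bracket is narrower than ``tol``; an interval criterion is
    used rather than |charge| because the charge of a weakly ionizable peptide
    plateaus near zero over a wide pH band, where a charge criterion would
    stop far from the root.  At the default tol the residual charge is well
    below 1e-4.
    """
    if not seq:
        raise DomainError("empty sequence")
    lo, hi = 0.0, 14.0
    while (hi - lo) >= tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# --- distribution visualization and comparison -------------------------------


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def silverman_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5) (rule-of-thumb for Gaussian kernels)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-0.2)


def kde(values: Sequence[float], bandwidth: float | None = None, n_grid: int = 512) -> DensityCurve:
    """Gaussian-kernel density on a grid spanning the data range +/- 4 bandwidths."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no values for density estimation")
    if bandwidth is None:
        if np.unique(values).size < 2:
            raise ParameterError(
                "all values identical: pass an explicit bandwidth for a point mass"
            )
        bandwidth = silverman_bandwidth(values)
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    grid = np.linspace(values.min() - 4 * bandwidth, values.max() + 4 * bandwidth, n_grid)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bandwidth * math.sqrt(2 * math.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=float(bandwidth))


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    log_space: bool,
    label: str = "property",
) -> tuple[float, float, float]:
    """Welch's t-test between two groups; returns (t, Satterthwaite df, two-sided p).

    With ``log_space`` the comparison runs on log10 values, which requires all
    inputs strictly positive; a violation names the offending property.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if log_space:
        if np.any(a <= 0) or np.any(b <= 0):
            raise DomainError(
                f"log-space comparison of {label!r} requires strictly positive values"
            )
        a = np.log10(a)
        b = np.log10(b)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# --- per-protein profiles -----------------------------------------------------


def property_profiles(
    proteome: Mapping[str, str],
    background_freqs: np.ndarray,
    scale_set: Mapping[str, PropertyScale] | None = None,
    n_null: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw and z-normalized property means, pI, and length for every sequence.

    Nulls are length-matched: one Monte-Carlo panel per distinct sequence
    length, derived deterministically from ``seed`` and the length.
    """
    if scale_set is None:
        scale_set = _scales.DEFAULT_SCALES
    panels: dict[int, dict[str, NullDistribution]] = {}
    rows = []
    for pid, seq in proteome.items():
        n_std = sum(aa in AA_INDEX for aa in seq)
        if n_std == 0:
            continue
        if n_std not in panels:
            # per-length seed below 2**31, deterministic in (seed, length)
            sub = None if seed is None else (seed * 1_000_003 + n_std) % (2**31 - 1)
            panels[n_std] = build_null_panel(
                scale_set, background_freqs, n_std, n=n_null, seed=sub
            )
        row: dict[str, object] = {"protein_id": pid, "length": len(seq)}
        for name, scale in scale_set.items():
            raw = raw_property(seq, scale)
            row[f"{name}_raw"] = raw
            row[f"{name}_z"] = normalize_property(raw, panels[n_std][name])
        row["pI"] = isoelectric_point(seq)
        rows.append(row)
    if not rows:
        raise DomainError("no sequence with standard residues")
    return pd.DataFrame(rows)


def compare_profiles(
    interactors: pd.DataFrame, background: pd.DataFrame
) -> pd.DataFrame:
    """Group comparison of every profiled property between two profile tables.

    z-scores are compared on the raw scale (they can be negative); pI and
    length, strictly positive, are compared in log space.  One row per
    property with the scale used, Welch t, df and p.
    """
    rows = []
    for col in [c for c in interactors.columns if c.endswith("_z")] + ["pI", "length"]:
        log_space = col in ("pI", "length")
        t, df, p = compare_groups(
            interactors[col], background[col], log_space=log_space, label=col
        )
        rows.append(
            {
                "property": col,
                "scale": "log10" if log_space else "raw",
                "t": t,
                "df": df,
                "p_value": p,
                "mean_interactors": float(interactors[col].mean()),
                "mean_background": float(background[col].mean()),
            }
        )
    return pd.DataFrame(rows)
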