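"""Synthetic co-IP and proteome data with planted ground truth.

The co-IP generator emulates the study design the scoring pipeline targets:
four control and four heat-stress immunoprecipitation runs (two of each with
chemical crosslinker), log-normal protein abundances spanning the typical
label-free dynamic range, a planted subset of true interactors whose stress
intensities are shifted up by a fold change, and intensity-dependent dropout
(logistic detection probability), so that low-abundance proteins — including
true interactors enriched only under stress — routinely go missing in all
control runs.  The bait itself is simulated as the most abundant planted
protein.

The proteome generator draws i.i.d. residues from a fixed frequency vector
and plants a composition-shifted subset (by default acid-enriched and
helix-depleted) emulating the property bias of a chaperone substrate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError
from .io_formats import QuantTable
from .scales import AA_INDEX, AA_ORDER

#: background residue frequencies of a GC-rich algal proteome
#: (alanine-rich, in AA_ORDER)
DEFAULT_AA_FREQS = np.array(
    [
        0.120,  # A
        0.015,  # C
        0.050,  # D
        0.055,  # E
        0.030,  # F
        0.080,  # G
        0.020,  # H
        0.035,  # I
        0.045,  # K
        0.095,  # L
        0.020,  # M
        0.025,  # N
        0.060,  # P
        0.040,  # Q
        0.065,  # R
        0.075,  # S
        0.060,  # T
        0.080,  # V
        0.010,  # W
        0.020,  # Y
    ]
)

#: default composition shift of the planted interactor subset: mass moves
#: from basic (K, R) to acidic (D, E) residues and from helix formers (A, L)
#: to helix breakers (G, P); sums to zero.
DEFAULT_SHIFT_DELTAS = {
    "K": -0.015,
    "R": -0.020,
    "D": +0.015,
    "E": +0.020,
    "A": -0.030,
    "L": -0.020,
    "G": +0.030,
    "P": +0.020,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic co-IP experiment.

    Defaults mirror the study scale: 168 precipitated proteins of which 39
    are planted true interactors, 4 runs per condition, log10 replicate noise
    0.25, and a logistic detection curve whose midpoint sits one abundance
    standard deviation below the mean, so dropout concentrates at low
    intensity.
    """

    n_background: int = 129
    n_true: int = 39
    log2_enrichment: float = 2.5
    base_log10_mu: float = 7.0
    base_log10_sigma: float = 1.0
    replicate_sigma_log10: float = 0.25
    n_reps_per_condition: int = 4
    missing_midpoint_log10: float = 6.0
    missing_slope: float = 2.0
    include_bait: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_background < 1 or self.n_true < 0:
            raise ParameterError("protein counts must be positive")
        if self.n_reps_per_condition < 2:
            raise ParameterError("need at least 2 replicates per condition")
        if self.missing_slope <= 0:
            raise ParameterError("missingness slope must be > 0")
        if self.replicate_sigma_log10 <= 0 or self.base_log10_sigma <= 0:
            raise ParameterError("sigmas must be > 0")


@dataclass(frozen=True)
class SimTruth:
    """Planted labels and expected per-condition log10 intensities."""

    labels: dict[str, str]  # protein_id -> "planted_true" | "background"
    expected_log10: pd.DataFrame  # index protein_id, columns control/stress

    def planted(self) -> list[str]:
        return [p for p, l in self.labels.items() if l == "planted_true"]


def _design(n_reps: int) -> pd.DataFrame:
    rows = []
    for cond, prefix in (("control", "ctrl"), ("stress", "hs")):
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "run_id": f"{prefix}_{rep}",
                    "condition": cond,
                    "replicate": rep,
                    # half the runs per condition use crosslinker, as in the
                    # 2-of-4 study design
                    "crosslinker": rep > n_reps // 2,
                }
            )
    return pd.DataFrame(rows)


def simulate_coip(cfg: SimConfig) -> tuple[QuantTable, SimTruth]:
    """Draw one synthetic co-IP intensity table plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_background + cfg.n_true
    ids = [f"sim{i:04d}" for i in range(n)]
    planted = np.zeros(n, dtype=bool)
    planted[cfg.n_background :] = True

    base = rng.normal(cfg.base_log10_mu, cfg.base_log10_sigma, size=n)
    if cfg.include_bait and cfg.n_true > 0:
        # the bait analog: most abundant planted protein
        base[cfg.n_background] = cfg.base_log10_mu + 3.0 * cfg.base_log10_sigma
    shift = cfg.log2_enrichment * np.log10(2.0)
    mu_control = base
    mu_stress = base + np.where(planted, shift, 0.0)

    design = _design(cfg.n_reps_per_condition)
    cols = {}
    for _, run in design.iterrows():
        mu = mu_stress if run["condition"] == "stress" else mu_control
        log_int = mu + rng.normal(0.0, cfg.replicate_sigma_log10, size=n)
        p_detect = expit(cfg.missing_slope * (log_int - cfg.missing_midpoint_log10))
        detected = rng.random(n) < p_detect
        values = np.where(detected, 10.0**log_int, np.nan)
        cols[run["run_id"]] = values
    intensities = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))

    truth = SimTruth(
        labels={
            pid: ("planted_true" if flag else "background")
            for pid, flag in zip(ids, planted)
        },
        expected_log10=pd.DataFrame(
            {"control": mu_control, "stress": mu_stress}, index=ids
        ),
    )
    return QuantTable(intensities=intensities, design=design), truth


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Parameters of the synthetic proteome with a property-shifted subset."""

    n_proteins: int = 500
    length_min: int = 150
    length_max: int = 450
    frequencies: np.ndarray = field(default_factory=lambda: DEFAULT_AA_FREQS.copy())
    shifted_size: int = 40
    shift_deltas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SHIFT_DELTAS))
    seed: int = 0

    def shifted_frequencies(self) -> np.ndarray:
        deltas = np.zeros(20)
        for aa, d in self.shift_deltas.items():
            deltas[AA_INDEX[aa]] = d
        if abs(deltas.sum()) > 1e-9:
            raise ParameterError("frequency deltas must sum to 0")
        shifted = np.asarray(self.frequencies, dtype=float) + deltas
        if np.any(shifted < 0):
            raise ParameterError("frequency deltas produce a negative frequency")
        return shifted

    def validate(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (20,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ParameterError("frequencies must be a 20-vector summing to 1")
        if not (1 <= self.length_min <= self.length_max):
            raise ParameterError("invalid length range")
        if not (0 <= self.shifted_size <= self.n_proteins):
            raise ParameterError("shifted subset larger than proteome")
        self.shifted_frequencies()


def simulate_proteome(cfg: ProteomeSimConfig) -> tuple[dict[str, str], list[str]]:
    """Random proteome plus the id list of its composition-shifted subset."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(list(AA_ORDER))
    base_f = np.asarray(cfg.frequencies, dtype=float)
    shifted_f = cfg.shifted_frequencies()
    proteome: dict[str, str] = {}
    shifted_ids: list[str] = []
    for i in range(cfg.n_proteins):
        shifted = i < cfg.shifted_size
        pid = f"prot{i:05d}"
        length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
        freqs = shifted_f if shifted else base_f
        seq = "".join(aa[rng.choice(20, size=length, p=freqs / freqs.sum())])
        proteome[pid] = seq
        if shifted:
            shifted_ids.append(pid)
    return proteome, shifted_ids


def simulate_cleavage_table(
    proteome: dict[str, str],
    fraction_targeted: float,
    seed: int = 0,
    score_threshold: float = 0.5,
) -> dict[str, tuple[float, int]]:
    """Random targeting scores and cleavage positions for a proteome.

    Each protein is chloroplast-targeted (score above ``score_threshold``)
    with probability ``fraction_targeted``; cleavage positions are uniform on
    [0, min(60, length - 1)], so the mature sequence is never empty.
    """
    if not 0.0 <= fraction_targeted <= 1.0:
        raise ParameterError("fraction_targeted must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    table: dict[str, tuple[float, int]] = {}
    for pid, seq in proteome.items():
        targeted = rng.random() < fraction_targeted
        if targeted:
            score = float(rng.uniform(score_threshold + 1e-6, 1.0))
        else:
            score = float(rng.uniform(0.0, score_threshold))
        pos = int(rng.integers(0, min(60, len(seq) - 1) + 1))
        table[pid] = (score, pos)
    return table


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a co-IP config with a different seed."""
    return replace(cfg, seed=seed)
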