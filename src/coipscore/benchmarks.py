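"""Repeatable study experiments on synthetic data.

These drivers define the simulation studies the package is evaluated with:
operating characteristics of the interactor-calling procedure (realized
false-discovery proportion, recall, null calibration), calibration of the
Monte-Carlo property normalization, agreement of the pI solver with a grid
scan, and the directional property shift of a planted interactor subset.
Each takes a base seed and derives per-replicate seeds below 2**31.
"""

from __future__ import annotations

import math

import numpy as np

from . import properties, scoring
from .scales import DEFAULT_SCALES
from .simulate import (
    DEFAULT_AA_FREQS,
    ProteomeSimConfig,
    SimConfig,
    simulate_coip,
    simulate_proteome,
)


def _subseed(seed: int, k: int) -> int:
    return (seed * 10_007 + k) % (2**31 - 1)


def fdr_power_experiment(
    seed: int = 0,
    n_seeds: int = 20,
    n_background: int = 150,
    n_true: int = 40,
    log2_enrichment: float = 2.5,
    replicate_sigma_log10: float = 0.25,
    threshold: float = 0.05,
) -> dict[str, float]:
    """Mean realized FDP among called interactors and recall of planted
    proteins in the upper half of planted stress intensity, over replicates."""
    fdps, recalls, n_called = [], [], []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_background=n_background,
            n_true=n_true,
            log2_enrichment=log2_enrichment,
            replicate_sigma_log10=replicate_sigma_log10,
            seed=_subseed(seed, k),
        )
        q, truth = simulate_coip(cfg)
        records, _, _ = scoring.score_quant_table(q, threshold=threshold)
        called = set(scoring.call_interactors(records, threshold=threshold))
        planted = set(truth.planted())
        fdps.append(len(called - planted) / len(called) if called else 0.0)
        exp_stress = truth.expected_log10.loc[sorted(planted), "stress"]
        upper = set(exp_stress[exp_stress >= exp_stress.median()].index)
        recalls.append(len(called & upper) / len(upper))
        n_called.append(len(called))
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_recall_upper_half": float(np.mean(recalls)),
        "mean_n_called": float(np.mean(n_called)),
        "n_seeds": n_seeds,
    }


def null_calibration_experiment(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Fraction of training proteins labeled true when nothing is enriched."""
    fractions = []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_background=150,
            n_true=40,
            log2_enrichment=0.0,
            include_bait=False,
            seed=_subseed(seed, k),
        )
        q, _ = simulate_coip(cfg)
        training, _ = scoring.build_training_set(q)
        fractions.append(
            sum(t.label == scoring.TRUE_INTERACTOR for t in training) / len(training)
        )
    return {"mean_true_label_fraction": float(np.mean(fractions)), "n_seeds": n_seeds}


def z_calibration_experiment(
    seed: int = 0, n: int = 5000, length: int = 200
) -> dict[str, tuple[float, float]]:
    """Mean and sd of z over fresh null-law sequences, per property scale.

    Both should be near 0 and 1: the normalization is judged against draws it
    has never seen, generated from the same residue frequencies.
    """
    freqs = DEFAULT_AA_FREQS
    panel = properties.build_null_panel(DEFAULT_SCALES, freqs, length, n=n, seed=seed)
    rng = np.random.default_rng(_subseed(seed, 1))
    idx = rng.choice(20, size=(n, length), p=freqs)
    out = {}
    for name, scale in DEFAULT_SCALES.items():
        draws = scale.vector[idx].mean(axis=1)
        null = panel[name]
        z = (draws - null.mu) / null.sigma
        out[name] = (float(z.mean()), float(z.std(ddof=1)))
    return out


def pi_grid_experiment(seed: int = 0, n_sequences: int = 50) -> float:
    """Max |bisection - grid-scan| disagreement in pH units over random sequences."""
    from .scales import AA_ORDER

    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 14.0001, 1e-3)
    worst = 0.0
    for _ in range(n_sequences):
        seq = "".join(rng.choice(list(AA_ORDER), size=int(rng.integers(5, 120))))
        pi = properties.isoelectric_point(seq)
        charges = np.array([properties.net_charge(seq, ph) for ph in grid])
        worst = max(worst, abs(pi - grid[np.argmin(np.abs(charges))]))
    return worst


def property_shift_experiment(
    seed: int = 0,
    n_proteins: int = 340,
    shifted_size: int = 40,
    n_null: int = 5000,
) -> dict[str, float]:
    """Directional property comparison of an acid-enriched, helix-depleted
    planted subset against its background proteome."""
    cfg = ProteomeSimConfig(n_proteins=n_proteins, shifted_size=shifted_size, seed=seed)
    proteome, shifted = simulate_proteome(cfg)
    shifted_set = set(shifted)
    freqs = properties.aa_frequencies(proteome)
    prof = properties.property_profiles(proteome, freqs, n_null=n_null, seed=seed)
    is_shifted = prof["protein_id"].isin(shifted_set)
    sub, bg = prof[is_shifted], prof[~is_shifted]

    t_hel, _, p_hel = properties.compare_groups(
        sub["helicity_z"], bg["helicity_z"], log_space=False, label="helicity_z"
    )
    t_pi, _, p_pi = properties.compare_groups(
        sub["pI"], bg["pI"], log_space=True, label="pI"
    )
    return {
        "helicity_z_mean_diff": float(sub["helicity_z"].mean() - bg["helicity_z"].mean()),
        "helicity_p": p_hel,
        "pi_mean_diff": float(sub["pI"].mean() - bg["pI"].mean()),
        "pi_p": p_pi,
        "n_shifted": int(is_shifted.sum()),
        "n_background": int((~is_shifted).sum()),
    }


def default_run_counts(seed: int = 0) -> dict[str, float]:
    """Identified / trained / called counts of one default-scale synthetic run."""
    q, _ = simulate_coip(SimConfig(seed=seed))
    records, _, model = scoring.score_quant_table(q)
    return {
        "n_identified": len(records),
        "n_trained": sum(r.in_training_set for r in records),
        "n_called": len(scoring.call_interactors(records)),
        "min_error_probability": float(model.e.min()),
    }
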