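#!/usr/bin/env python
"""Generate the synthetic datasets the downstream analyses consume.

Two co-IP scenarios at the study scale (129 background + 39 planted
interactors, 4 control + 4 heat-stress runs):

* ``moderate``  — +2.5 log2 enrichment, sigma_log10 0.25: a hard regime in
  which differential tests label true interactors with only partial power.
* ``strong``    — +8 log2 enrichment, sigma_log10 0.15: a strongly induced
  bait whose partners are essentially absent from control precipitates, the
  regime the error-probability curve was designed for.

Plus one synthetic proteome (340 proteins) whose first 40 sequences are
acid-enriched and helix-depleted, emulating a chaperone-substrate subset.
"""

from pathlib import Path

from coipscore.io_formats import write_fasta, write_quant_table, write_results
from coipscore.simulate import (
    ProteomeSimConfig,
    SimConfig,
    simulate_cleavage_table,
    simulate_coip,
    simulate_proteome,
)

OUT = Path("results/data")
SEED = 0

SCENARIOS = {
    "moderate": SimConfig(seed=SEED),
    "strong": SimConfig(log2_enrichment=8.0, replicate_sigma_log10=0.15, seed=SEED),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, cfg in SCENARIOS.items():
        q, truth = simulate_coip(cfg)
        d = OUT / name
        d.mkdir(exist_ok=True)
        write_quant_table(q, d / "quant.tsv", d / "design.tsv")
        frame = truth.expected_log10.copy()
        frame.insert(0, "label", [truth.labels[p] for p in frame.index])
        frame.index.name = "protein_id"
        write_results(frame.reset_index(), d / "truth.tsv")
        n_missing = int(q.intensities.isna().sum().sum())
        print(
            f"{name}: {len(q.protein_ids)} proteins x {len(q.run_ids)} runs, "
            f"{n_missing} missing cells ({n_missing / q.intensities.size:.0%})"
        )

    pcfg = ProteomeSimConfig(n_proteins=340, shifted_size=40, seed=SEED)
    proteome, shifted = simulate_proteome(pcfg)
    write_fasta(proteome, OUT / "proteome.fasta")
    (OUT / "shifted_ids.txt").write_text("".join(p + "\n" for p in shifted))
    cleav = simulate_cleavage_table(proteome, fraction_targeted=0.9, seed=SEED)
    with open(OUT / "cleavage.tsv", "w") as fh:
        fh.write("protein_id\ttargeting_score\tcleavage_position\n")
        for pid, (score, pos) in cleav.items():
            fh.write(f"{pid}\t{score:.6f}\t{pos}\n")
    print(f"proteome: {len(proteome)} sequences, {len(shifted)} composition-shifted")


if __name__ == "__main__":
    main()
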