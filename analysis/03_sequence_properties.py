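#!/usr/bin/env python
"""Compare sequence properties of the planted interactor-like subset against
the mature synthetic proteome.

Reads the simulated proteome, strips predicted transit peptides, computes
Monte-Carlo-normalized property indices and isoelectric points for the
composition-shifted subset versus the background, and reports the Welch
comparison per property.
"""

from pathlib import Path

from coipscore.io_formats import read_results
from coipscore.pipeline import PipelineConfig, run_props_stage

DATA = Path("results/data")
OUT = Path("results/properties")
SEED = 0


def main() -> None:
    cfg = PipelineConfig(
        fasta_path=DATA / "proteome.fasta",
        cleavage_path=DATA / "cleavage.tsv",
        interactors_path=DATA / "shifted_ids.txt",
        n_null=5000,
        seed=SEED,
        out_dir=OUT,
    )
    props_out = run_props_stage(cfg, [], OUT)
    print(
        f"profiled {props_out['n_interactors_profiled']} interactor-like vs "
        f"{props_out['n_background_profiled']} background sequences "
        f"({props_out['sequence_form']})"
    )
    comparison = read_results(OUT / "comparison.tsv")
    for _, row in comparison.iterrows():
        direction = "lower" if row["mean_interactors"] < row["mean_background"] else "higher"
        print(
            f"  {row['property']:<18} interactors {direction} "
            f"(means {row['mean_interactors']:.3f} vs {row['mean_background']:.3f}, "
            f"p = {row['p_value']:.3g})"
        )


if __name__ == "__main__":
    main()
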