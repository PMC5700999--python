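"""Readers and writers for the tabular and sequence formats the pipeline touches.

Conventions fixed here and used everywhere else:

* A stored intensity of zero, an empty cell, or ``.`` all mean "protein not
  detected in that run" and are normalized to missing (NaN) on read.
* Cleavage positions are 1-based and denote the *last* residue of the transit
  peptide; the mature sequence starts at ``position + 1``.
* Non-standard residues (X, B, Z, U, ...) are retained on read; the property
  modules decide how to treat them.
* The output NA token is ``NA``; numeric fields round-trip to 6 significant
  digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError

CONDITIONS = ("control", "stress")

#: tokens accepted as "not detected" in intensity tables
MISSING_TOKENS = {"", ".", "0", "0.0", "NA", "NaN", "nan"}

NA_TOKEN = "NA"


@dataclass(frozen=True)
class QuantTable:
    """Protein x run intensity matrix with an explicit missing state.

    ``intensities`` is indexed by protein id with one column per run, in the
    order of ``design``; missing cells are NaN, all stored values are > 0.
    ``design`` has columns run_id, condition, replicate, crosslinker.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def runs(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        mask = self.design["condition"] == condition
        return list(self.design.loc[mask, "run_id"])

    def values_for(self, protein_id: str, condition: str) -> np.ndarray:
        """Non-missing intensities of one protein in one condition."""
        if protein_id not in self.intensities.index:
            raise KeyError(f"unknown protein {protein_id!r}")
        row = self.intensities.loc[protein_id, self.runs(condition)]
        return row.dropna().to_numpy(dtype=float)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a run design TSV (columns run_id, condition, replicate, crosslinker)."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = ["run_id", "condition", "replicate", "crosslinker"]
    missing_cols = [c for c in required if c not in design.columns]
    if missing_cols:
        raise FormatError(f"design file {path} lacks columns {missing_cols}")
    design = design[required].copy()
    if design["run_id"].duplicated().any():
        dup = design.loc[design["run_id"].duplicated(), "run_id"].iloc[0]
        raise FormatError(f"duplicate run_id {dup!r} in design")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"conditions must be in {CONDITIONS}, found {sorted(bad)}")
    counts = design["condition"].value_counts()
    for cond in CONDITIONS:
        if counts.get(cond, 0) < 2:
            raise FormatError(f"need at least 2 runs for condition {cond!r}")
    try:
        design["replicate"] = design["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate index: {exc}") from exc
    if (design["replicate"] < 1).any():
        raise FormatError("replicate indices must be positive")
    design["crosslinker"] = design["crosslinker"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if design["crosslinker"].isna().any():
        raise FormatError("crosslinker flags must be boolean (true/false/1/0)")
    return design.reset_index(drop=True)


def read_quant_table(path: str | Path, design_path: str | Path) -> QuantTable:
    """Read a MaxQuant-proteinGroups-like intensity TSV plus its run design.

    Row 1 must be ``protein_id`` followed by run ids; zeros and blanks become
    missing; columns are aligned to design order regardless of file order.
    """
    design = read_design(design_path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if table.columns[0] != "protein_id":
        raise FormatError(f"first column of {path} must be 'protein_id'")
    table = table.set_index("protein_id")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise FormatError(f"duplicate protein id {dup!r}")
    file_runs = set(table.columns)
    design_runs = set(design["run_id"])
    if file_runs != design_runs:
        raise FormatError(
            f"run ids disagree between intensity table and design: "
            f"only in table {sorted(file_runs - design_runs)}, "
            f"only in design {sorted(design_runs - file_runs)}"
        )

    def _parse(cell: str) -> float:
        token = cell.strip()
        if token in MISSING_TOKENS:
            return np.nan
        try:
            value = float(token)
        except ValueError as exc:
            raise FormatError(f"unparseable intensity {cell!r}") from exc
        if value < 0:
            raise FormatError(f"negative intensity {value}")
        return value if value > 0 else np.nan

    values = table.map(_parse)
    values = values[list(design["run_id"])]  # align column order to the design
    values.index.name = "protein_id"
    return QuantTable(intensities=values.astype(float), design=design)


def write_quant_table(q: QuantTable, path: str | Path, design_path: str | Path) -> None:
    """Write a QuantTable and its design in the formats :func:`read_quant_table` reads.

    Missing cells are written as blanks; intensities keep full precision so a
    round trip is lossless up to float formatting.
    """
    frame = q.intensities.copy()
    frame.index.name = "protein_id"
    frame.to_csv(path, sep="\t", na_rep="")
    q.design.to_csv(design_path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> upper-case sequence mapping.

    The id is the first whitespace-delimited token of the header.
    """
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id!r}")
        if record.id in proteome:
            raise FormatError(f"duplicate sequence id {record.id!r}")
        proteome[record.id] = seq
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_cleavage_table(path: str | Path) -> dict[str, tuple[float, int]]:
    """Read a targeting/cleavage TSV: protein_id, targeting_score, cleavage_position.

    Positions are 1-based indices of the last transit-peptide residue;
    position 0 means "no transit peptide".
    """
    table: dict[str, tuple[float, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] in ("protein_id", "id"):
                continue  # optional header
            if len(fields) != 3:
                raise FormatError(f"line {lineno}: expected 3 columns, got {len(fields)}")
            pid, score_s, pos_s = fields
            try:
                score = float(score_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad targeting score {score_s!r}") from exc
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer cleavage position {pos_s!r}") from exc
            if pos < 0:
                raise FormatError(f"line {lineno}: negative cleavage position {pos}")
            if pid in table:
                raise FormatError(f"line {lineno}: duplicate protein id {pid!r}")
            table[pid] = (score, pos)
    return table


def write_results(records, path: str | Path, columns: list[str] | None = None) -> None:
    """Write a list of result records (dataclasses or dicts) to TSV.

    Column order is the field order of the first record (deterministic);
    floats are written with 6 significant digits; missing values as ``NA``.
    An empty record list writes a header-only file (``columns`` supplies the
    header when it cannot be inferred).
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        rows = [r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in records]
        frame = pd.DataFrame(rows, columns=columns if not rows else None)
    frame.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
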