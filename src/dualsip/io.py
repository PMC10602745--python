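"""Table I/O with provenance headers.

All stage inputs and outputs are plain CSV/TSV. Output files carry a leading
comment block (``# key = value``) recording every parameter that shaped the
table, so no run depends on silent defaults; readers skip those lines.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from .dna import BottleSet, FractionProfile
from .isotopes import delta13c, delta_d
from .plfa import PlfaMeasurement, parse_plfa_name

DNA_COLUMNS = ["bottle_id", "treatment", "replicate_role", "fraction_id",
               "density_g_ml", "dna_ng", "taxon", "reads"]
PLFA_COLUMNS = ["well", "treatment", "timepoint", "plfa_name",
                "conc_pmol_per_l", "delta13c_permil", "deltad_permil"]
PEAK_COLUMNS = ["feature_id", "mz", "intensity", "rt"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_table(df: pd.DataFrame, path: str | Path,
                provenance: Mapping[str, object] | None = None) -> Path:
    """Write a table with a ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# -- DNA-SIP long form -------------------------------------------------------

def bottleset_to_frame(bottles: BottleSet) -> pd.DataFrame:
    """Flatten a BottleSet into the long-form gradient table."""
    rows = []

    def emit(bottle, role: str, bottle_id: str) -> None:
        for frac in bottle:
            # a zero-read placeholder keeps read-empty fractions in the table
            items = sorted(frac.counts.items()) or [("none", 0)]
            for taxon, reads in items:
                rows.append({
                    "bottle_id": bottle_id, "treatment": bottles.treatment,
                    "replicate_role": role, "fraction_id": frac.fraction_id,
                    "density_g_ml": frac.density, "dna_ng": frac.dna_mass,
                    "taxon": taxon, "reads": reads,
                })

    for i, rep in enumerate(bottles.labeled_replicates, start=1):
        emit(rep, f"labeled_{i}", f"{bottles.well}_L{i}")
    emit(bottles.control_bottle, "control", f"{bottles.well}_C")
    return pd.DataFrame(rows, columns=DNA_COLUMNS)


def frame_to_bottleset(df: pd.DataFrame, well: str = "",
                       t0_counts: Mapping[str, int] | None = None) -> BottleSet:
    """Rebuild a BottleSet from the long-form gradient table."""
    missing = set(DNA_COLUMNS) - {"dna_ng"} - set(df.columns)
    if missing:
        raise ValueError(f"gradient table missing columns: {sorted(missing)}")

    def build(sub: pd.DataFrame) -> list[FractionProfile]:
        fractions = []
        for (fid, density), grp in sub.groupby(["fraction_id", "density_g_ml"]):
            counts = {t: int(r) for t, r in zip(grp["taxon"], grp["reads"])
                      if int(r) > 0}
            dna = float(grp["dna_ng"].iloc[0]) if "dna_ng" in grp else 0.0
            fractions.append(FractionProfile(
                fraction_id=int(fid), density=float(density),
                dna_mass=dna, counts=counts,
            ))
        return sorted(fractions, key=lambda f: f.fraction_id)

    roles = sorted(df["replicate_role"].unique())
    labeled_roles = [r for r in roles if r.startswith("labeled")]
    if "control" not in roles:
        raise ValueError("gradient table has no control bottle")
    labeled = [build(df[df["replicate_role"] == r]) for r in labeled_roles]
    control = build(df[df["replicate_role"] == "control"])
    treatment = df["treatment"].iloc[0]
    well = well or str(df.get("bottle_id", pd.Series([""])).iloc[0]).split("_")[0]
    return BottleSet(treatment=treatment, well=well,
                     labeled_replicates=labeled, control_bottle=control,
                     t0_counts=dict(t0_counts or {}))


# -- PLFA --------------------------------------------------------------------

def frame_to_plfa_pairs(df: pd.DataFrame
                        ) -> list[tuple[PlfaMeasurement, PlfaMeasurement]]:
    """Pair T0 and Tend measurements per lipid from a PLFA table."""
    missing = set(PLFA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PLFA table missing columns: {sorted(missing)}")
    pairs = []
    for name_raw, grp in df.groupby("plfa_name"):
        by_tp = {}
        for _, row in grp.iterrows():
            by_tp[row["timepoint"]] = PlfaMeasurement(
                name=parse_plfa_name(str(name_raw)),
                timepoint=row["timepoint"],
                concentration=float(row["conc_pmol_per_l"]),
                delta_13c=delta13c(float(row["delta13c_permil"])),
                delta_d=delta_d(float(row["deltad_permil"])),
                treatment=str(row.get("treatment", "")),
                well=str(row.get("well", "")),
            )
        if "T0" in by_tp and "Tend" in by_tp:
            pairs.append((by_tp["T0"], by_tp["Tend"]))
    return pairs
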