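"""Gibbs free-energy layer: ΔG°, ΔΔG° transition tables, and affinity ratios.

ΔG° = −RT ln K_as with K_as on the molar scale (standard state 1 M); a
ligand transition A→B for one protein is ΔΔG° = ΔG°(B) − ΔG°(A) =
−RT ln(K_B/K_A), in which the concentration scale cancels.  Uncertainties
propagate to first order from the relative errors of the two pooled
constants, assumed independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .binding_model import ValidationError
from .titration_fit import AffinityRecord

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872041e-3
#: default temperature (20 °C), K
T_DEFAULT = 293.15
#: μM^-1 -> M^-1
_UM_TO_M = 1e6


def delta_g(kas: float, temperature: float = T_DEFAULT) -> float:
    """Standard binding free energy ΔG° (kcal/mol) from K_as in μM⁻¹."""
    if kas <= 0:
        raise ValidationError(f"kas must be positive, got {kas}")
    if temperature <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    return -R_KCAL * temperature * np.log(kas * _UM_TO_M)


@dataclass
class TransitionEnergy:
    """ΔΔG° ± σ (kcal/mol) for a ligand transition A→B of one protein."""

    protein_id: str
    from_ligand: str
    to_ligand: str
    ddg: float
    ddg_se: float
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.ddg_se < 0:
            raise ValidationError("ddg_se must be >= 0")


def delta_delta_g(
    rec_from: AffinityRecord,
    rec_to: AffinityRecord,
    temperature: float = T_DEFAULT,
    *,
    allow_cross_buffer: bool = False,
) -> TransitionEnergy:
    """ΔΔG° for the transition rec_from → rec_to of a single protein.

    Negative values mean the destination ligand binds tighter ("energy
    gain").  By default both records must share protein and buffer; pass
    allow_cross_buffer=True for deliberate e.g. glycerol comparisons.
    """
    if rec_from.protein_id != rec_to.protein_id:
        raise ValidationError(
            f"transition across proteins: {rec_from.protein_id} vs {rec_to.protein_id}"
        )
    if not allow_cross_buffer and rec_from.buffer_tag != rec_to.buffer_tag:
        raise ValidationError(
            f"transition across buffers: {rec_from.buffer_tag} vs {rec_to.buffer_tag} "
            "(pass allow_cross_buffer=True if intended)"
        )
    rt = R_KCAL * temperature
    ddg = -rt * np.log(rec_to.kas / rec_from.kas)
    ddg_se = rt * np.sqrt(
        (rec_from.kas_se / rec_from.kas) ** 2 + (rec_to.kas_se / rec_to.kas) ** 2
    )
    return TransitionEnergy(
        protein_id=rec_from.protein_id,
        from_ligand=rec_from.ligand,
        to_ligand=rec_to.ligand,
        ddg=float(ddg),
        ddg_se=float(ddg_se),
        temperature=temperature,
    )


def affinity_ratio(rec_a: AffinityRecord, rec_b: AffinityRecord) -> float:
    """Dimensionless K_as ratio a/b (e.g. eIF4E1a over eIF4E1b, same ligand)."""
    if rec_a.kas <= 0 or rec_b.kas <= 0:
        raise ValidationError("affinity ratio needs positive kas in both records")
    return rec_a.kas / rec_b.kas


def round_ratio(value: float, decimals: int = 2) -> float:
    """Display rounding for ratio columns (banker's rounding, two decimals)."""
    return round(value, decimals)


# --- tabular layer ----------------------------------------------------------


def read_kas_table(path=None) -> pd.DataFrame:
    """Read an association-constant TSV (protein, ligand, buffer, kas_uM_inv, se, n).

    Without a path, loads the bundled table of measured cap affinities for
    human/Xenopus eIF4E1a and eIF4E1b proteins.
    """
    if path is None:
        text = resources.files("capbind").joinpath("data/kas_table.tsv").read_text()
        df = pd.read_csv(StringIO(text), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"protein", "ligand", "buffer", "kas_uM_inv", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"kas table missing columns: {sorted(missing)}")
    if "n" not in df.columns:
        df["n"] = 1
    return df


def read_transitions(path=None) -> list[tuple[str, str]]:
    """Read a transition list TSV (columns from_ligand, to_ligand)."""
    if path is None:
        text = resources.files("capbind").joinpath("data/ddg_transitions.tsv").read_text()
        df = pd.read_csv(StringIO(text), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return list(zip(df["from_ligand"], df["to_ligand"]))


def records_from_table(df: pd.DataFrame) -> list[AffinityRecord]:
    return [
        AffinityRecord(
            protein_id=row["protein"],
            ligand=row["ligand"],
            buffer_tag=row["buffer"],
            kas=float(row["kas_uM_inv"]),
            kas_se=float(row["se"]),
            n_replicates=int(row.get("n", 1)),
        )
        for _, row in df.iterrows()
    ]


def build_ddg_table(
    records: list[AffinityRecord] | pd.DataFrame,
    transitions: list[tuple[str, str]],
    temperature: float = T_DEFAULT,
) -> pd.DataFrame:
    """ΔΔG° table: one row per (protein, buffer, transition).

    A transition whose ligands are not both measured for a protein×buffer
    appears as an explicit gap row (NaN energies) so printed tables can show
    a dash.  A transition naming a ligand absent from every record raises.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_table(records)
    if not transitions:
        return pd.DataFrame(
            columns=["protein", "buffer", "from", "to", "ddg_kcal_mol", "se", "gap"]
        )
    known_ligands = {r.ligand for r in records}
    for a, b in transitions:
        for lig in (a, b):
            if lig not in known_ligands:
                raise ValidationError(
                    f"transition names unknown ligand {lig!r}; known: "
                    f"{sorted(known_ligands)}"
                )
    by_cell: dict[tuple[str, str], dict[str, AffinityRecord]] = {}
    for r in records:
        by_cell.setdefault((r.protein_id, r.buffer_tag), {})[r.ligand] = r
    rows = []
    for (protein, buffer_tag), ligmap in by_cell.items():
        for a, b in transitions:
            if a in ligmap and b in ligmap:
                te = delta_delta_g(ligmap[a], ligmap[b], temperature)
                rows.append(
                    {
                        "protein": protein,
                        "buffer": buffer_tag,
                        "from": a,
                        "to": b,
                        "ddg_kcal_mol": te.ddg,
                        "se": te.ddg_se,
                        "gap": False,
                    }
                )
            else:
                rows.append(
                    {
                        "protein": protein,
                        "buffer": buffer_tag,
                        "from": a,
                        "to": b,
                        "ddg_kcal_mol": np.nan,
                        "se": np.nan,
                        "gap": True,
                    }
                )
    return pd.DataFrame(rows)


def build_ratio_table(
    records: list[AffinityRecord] | pd.DataFrame,
    protein_a: str,
    protein_b: str,
    *,
    buffer_a: str | None = None,
    buffer_b: str | None = None,
) -> pd.DataFrame:
    """Per-ligand K_as(protein_a)/K_as(protein_b) ratios.

    Ratios are taken within a buffer unless buffer_a/buffer_b are given
    explicitly (the two proteins may have been measured in different
    buffers, e.g. the glycerol-stabilized one).  Returns raw and two-decimal
    display ratios.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_table(records)

    def select(protein, buffer_tag):
        chosen: dict[str, AffinityRecord] = {}
        for r in records:
            if r.protein_id != protein:
                continue
            if buffer_tag is not None and r.buffer_tag != buffer_tag:
                continue
            if r.ligand in chosen:
                raise ValidationError(
                    f"{protein} has {r.ligand!r} in more than one buffer; "
                    "pass buffer_a/buffer_b explicitly"
                )
            chosen[r.ligand] = r
        return chosen

    sel_a = select(protein_a, buffer_a)
    sel_b = select(protein_b, buffer_b)
    rows = []
    for lig in sel_a:
        if lig in sel_b:
            ratio = affinity_ratio(sel_a[lig], sel_b[lig])
            rows.append(
                {
                    "ligand": lig,
                    "ratio": ratio,
                    "ratio_2dp": round_ratio(ratio),
                }
            )
    return pd.DataFrame(rows)
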