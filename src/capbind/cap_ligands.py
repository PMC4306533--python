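"""Cap-analogue chemistry: name parsing, catalogue, and net charge vs pH.

A 5′-cap analogue is described by its guanine-ring modification (alkylation at
N7, optional dimethylation at N2), the length of its phosphate chain, an
optional second nucleoside (making it a dinucleotide, m7GpppN), and optional
2′-O-ribose methylation.  Net charge at a given pH is estimated from the
fully protonated reference charge plus independent Henderson–Hasselbalch
fractional deprotonation of each ionizable group (the N1 proton of
7-alkylguanine, pK_a1, and the secondary proton of the terminal phosphate,
pK_a2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml


class LigandParseError(ValueError):
    """Cap-analogue name does not follow the recognized grammar."""


class LigandValidationError(ValueError):
    """Parsed modifiers are chemically contradictory."""


@dataclass(frozen=True)
class IonizableGroup:
    """One ionizable proton: label, pKa, and charge change on deprotonation."""

    label: str
    pKa: float
    deprotonated_delta: int = -1

    def __post_init__(self) -> None:
        if not (0 < self.pKa < 14):
            raise LigandValidationError(f"pKa out of range (0, 14): {self.pKa}")


_N7_MODS = ("none", "methyl", "ethyl", "benzyl")
_RIBOSE = ("none", "first", "second")


@dataclass(frozen=True)
class CapAnalogue:
    """A cap ligand's chemistry.

    base_charge is the net charge with every listed ionizable group in its
    protonated state; deprotonation deltas are added fractionally by
    :func:`net_charge`.
    """

    name: str
    n7_mod: str = "none"
    n2_methyls: int = 0
    phosphate_count: int = 1
    second_nucleoside: str = "none"
    ribose_2O_methyl: str = "none"
    base_charge: float = 0.0
    ionizable_groups: tuple[IonizableGroup, ...] = ()

    def __post_init__(self) -> None:
        if self.n7_mod not in _N7_MODS:
            raise LigandValidationError(f"unknown n7_mod {self.n7_mod!r}")
        if self.n2_methyls not in (0, 2):
            raise LigandValidationError("n2_methyls must be 0 or 2")
        if self.n2_methyls == 2 and self.n7_mod != "methyl":
            raise LigandValidationError(
                "N2 dimethylation only occurs on the N7-methylated ring (m2,2,7G)"
            )
        if not 1 <= self.phosphate_count <= 5:
            raise LigandValidationError(
                f"phosphate_count must be in 1..5, got {self.phosphate_count}"
            )
        if self.second_nucleoside not in ("none", "G", "A"):
            raise LigandValidationError(
                f"second_nucleoside must be none/G/A, got {self.second_nucleoside!r}"
            )
        if self.ribose_2O_methyl not in _RIBOSE:
            raise LigandValidationError(
                f"ribose_2O_methyl must be none/first/second, got {self.ribose_2O_methyl!r}"
            )
        if self.second_nucleoside == "none" and self.ribose_2O_methyl != "none":
            raise LigandValidationError(
                "ribose 2'-O methylation positions are only defined for dinucleotides"
            )

    def canonical_name(self) -> str:
        """Render the canonical text label (inverse of parse_analogue_name)."""
        prefix = {"none": "", "methyl": "m7", "ethyl": "et7", "benzyl": "bn7"}[
            self.n7_mod
        ]
        if self.n2_methyls == 2:
            prefix = "m2,2,7"
        if self.ribose_2O_methyl == "first":
            prefix += ",2'O"
        if self.second_nucleoside != "none":
            mid = "pppm2'O" if self.ribose_2O_methyl == "second" else "ppp"
            return f"{prefix}G{mid}{self.second_nucleoside}"
        code = {1: "MP", 2: "DP", 3: "TP", 4: "p4", 5: "p5"}[self.phosphate_count]
        return f"{prefix}G{code}"


# Grammar: <n7 prefix>[,2'O]G(<MP|DP|TP|p4|p5> | ppp[m2'O]<G|A>)
_NAME_RE = re.compile(
    r"^(?P<n7>m7|et7|bn7|m2,2,7|m227)?"
    r"(?P<rib1>,2'O|,2O)?"
    r"G"
    r"(?:(?P<mono>MP|DP|TP|p4|p5)|ppp(?P<rib2>m2'O|m2O)?(?P<second>[GA]))$"
)

_PHOSPHATES = {"MP": 1, "DP": 2, "TP": 3, "p4": 4, "p5": 5}


def _default_groups(n7_mod: str, n2_methyls: int, second: str, pka1: float, pka2: float):
    """Illustrative default ionizable groups for a parsed analogue.

    N7-alkylated guanine carries an N1 proton titrating near neutral pH
    (pK_a1); mononucleotides additionally carry the secondary proton of the
    terminal phosphate (pK_a2).  Dinucleotide bridge phosphates are strong
    acids and contribute no group in the 0–14 range modeled here.
    """
    groups = []
    if n7_mod != "none":
        groups.append(IonizableGroup("N1-H (7-alkylguanine)", pka1, -1))
    if second == "none":
        groups.append(IonizableGroup("terminal phosphate -OH", pka2, -1))
    return tuple(groups)


def parse_analogue_name(
    name: str, *, pka1: float = 7.2, pka2: float = 6.5
) -> CapAnalogue:
    """Parse a cap-analogue label such as "m7GTP", "bn7GDP" or "m7GpppG".

    Returns a fully populated :class:`CapAnalogue` whose base charge and
    ionizable groups follow the illustrative defaults (override via the
    ligand catalogue for quantitative charge work).
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        # point at the first token that breaks the grammar
        token = name.strip().split("G")[0] or name.strip()
        raise LigandParseError(
            f"cannot parse cap-analogue name {name!r} (offending token {token!r})"
        )
    n7 = m.group("n7") or ""
    n2_methyls = 2 if n7 in ("m2,2,7", "m227") else 0
    n7_mod = {
        "": "none",
        "m7": "methyl",
        "et7": "ethyl",
        "bn7": "benzyl",
        "m2,2,7": "methyl",
        "m227": "methyl",
    }[n7]
    if m.group("rib1") and n7 == "":
        raise LigandParseError(f"2'-O token without an N7 prefix in {name!r}")
    second = m.group("second") or "none"
    phosphates = 3 if second != "none" else _PHOSPHATES[m.group("mono")]
    if m.group("rib1"):
        ribose = "first"
    elif m.group("rib2"):
        ribose = "second"
    else:
        ribose = "none"

    ring_charge = 1.0 if n7_mod != "none" else 0.0
    # fully protonated reference: mononucleotide retains the terminal
    # secondary phosphate proton; dinucleotide bridge is fully ionized
    base_charge = ring_charge - phosphates

    analogue = CapAnalogue(
        name="",  # placeholder, replaced below with canonical rendering
        n7_mod=n7_mod,
        n2_methyls=n2_methyls,
        phosphate_count=phosphates,
        second_nucleoside=second,
        ribose_2O_methyl=ribose,
        base_charge=base_charge,
        ionizable_groups=_default_groups(n7_mod, n2_methyls, second, pka1, pka2),
    )
    canonical = analogue.canonical_name()
    return CapAnalogue(
        name=canonical,
        n7_mod=analogue.n7_mod,
        n2_methyls=analogue.n2_methyls,
        phosphate_count=analogue.phosphate_count,
        second_nucleoside=analogue.second_nucleoside,
        ribose_2O_methyl=analogue.ribose_2O_methyl,
        base_charge=analogue.base_charge,
        ionizable_groups=analogue.ionizable_groups,
    )


def net_charge(analogue: CapAnalogue, pH: float) -> float:
    """Net charge at the given pH.

    base_charge + Σ_groups delta × 1/(1 + 10^(pKa − pH)): each group titrates
    independently (no coupling between sites).
    """
    charge = analogue.base_charge
    for g in analogue.ionizable_groups:
        charge += g.deprotonated_delta / (1.0 + 10.0 ** (g.pKa - pH))
    return charge


def load_catalogue(path=None) -> dict[str, CapAnalogue]:
    """Load a ligand catalogue (YAML list of {name, base_charge, groups}).

    Without a path, loads the bundled illustrative catalogue.  Entries are
    parsed from their names and then overridden by any explicit base_charge /
    groups fields.
    """
    if path is None:
        text = (
            resources.files("capbind").joinpath("data/ligand_catalogue.yaml").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    entries = yaml.safe_load(text)["ligands"]
    catalogue = {}
    for entry in entries:
        base = parse_analogue_name(entry["name"])
        groups = base.ionizable_groups
        if "groups" in entry:
            groups = tuple(
                IonizableGroup(g["label"], float(g["pKa"]), int(g.get("delta", -1)))
                for g in entry["groups"]
            )
        catalogue[base.name] = CapAnalogue(
            name=base.name,
            n7_mod=base.n7_mod,
            n2_methyls=base.n2_methyls,
            phosphate_count=base.phosphate_count,
            second_nucleoside=base.second_nucleoside,
            ribose_2O_methyl=base.ribose_2O_methyl,
            base_charge=float(entry.get("base_charge", base.base_charge)),
            ionizable_groups=groups,
        )
    return catalogue
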