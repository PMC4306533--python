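"""Comparative-sequence stage: family-discriminating alignment positions.

Given a multiple alignment of two paralog families (e.g. canonical eIF4E1a
vs oocyte-enriched eIF4E1b), a *discriminating position* is a column whose
modal residue is conserved within each family (at or above a threshold) but
differs between the families.  The module also scores the charge character
of N-terminal windows (eIF4E1b N-termini are basic, eIF4E1a acidic) and maps
residue numbering between orthologue conventions that differ by a fixed
offset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import yaml
from Bio import AlignIO

from .binding_model import ValidationError


class AlignmentFormatError(ValueError):
    """Unreadable or ragged alignment file."""


@dataclass
class LabelledAlignment:
    """Aligned sequences with a two-family labelling and a numbering reference."""

    sequences: list[tuple[str, str, str]]  # (id, family, aligned residues)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError("alignment is empty")
        length = len(self.sequences[0][2])
        for sid, _, seq in self.sequences:
            if len(seq) != length:
                raise AlignmentFormatError(f"ragged alignment: row {sid!r}")
        if self.reference_id not in {sid for sid, _, _ in self.sequences}:
            raise ValidationError(f"reference_id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0][2])

    def family(self, label: str) -> list[str]:
        return [seq for _, fam, seq in self.sequences if fam == label]

    @property
    def families(self) -> list[str]:
        seen: list[str] = []
        for _, fam, _ in self.sequences:
            if fam not in seen:
                seen.append(fam)
        return seen

    def reference_numbering(self, column: int) -> int | None:
        """1-based ungapped position of `column` in the reference sequence.

        None when the reference is gapped at that column.
        """
        ref = next(seq for sid, _, seq in self.sequences if sid == self.reference_id)
        if ref[column] == "-":
            return None
        return sum(1 for c in ref[: column + 1] if c != "-")


@dataclass
class DiscriminatingPosition:
    column: int  # 0-based alignment column
    reference_position: int | None  # 1-based in reference numbering, None if ref gapped
    consensus_a: str
    consensus_b: str
    conservation_a: float
    conservation_b: float
    near_site: str | None = None


def read_alignment(path, fmt: str, labels: dict[str, str], reference_id: str | None = None) -> LabelledAlignment:
    """Read an aligned FASTA ("fasta") or Clustal ("clustal") file.

    `labels` maps every sequence id to its family label; a missing id is a
    validation error.  The first labelled sequence is the default numbering
    reference.
    """
    if fmt not in ("fasta", "clustal"):
        raise AlignmentFormatError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentFormatError(str(exc)) from exc
    sequences = []
    for rec in aln:
        if rec.id not in labels:
            raise ValidationError(f"sequence {rec.id!r} has no family label")
        sequences.append((rec.id, labels[rec.id], str(rec.seq).upper()))
    return LabelledAlignment(
        sequences=sequences,
        reference_id=reference_id or sequences[0][0],
    )


def write_alignment(aln: LabelledAlignment, path, fmt: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, _, seq in aln.sequences]
    )
    AlignIO.write(msa, path, fmt)


def _column_consensus(column_residues: list[str], gap_policy: str):
    """(modal residue, conservation fraction) for one family in one column.

    gap_policy "strict": any gap in the family disqualifies the column
    (conservation 0).  "ignore": gapped rows are dropped before counting.
    """
    if gap_policy not in ("strict", "ignore"):
        raise ValidationError(f"unknown gap_policy {gap_policy!r}")
    if gap_policy == "strict" and "-" in column_residues:
        return None, 0.0
    residues = [r for r in column_residues if r != "-"]
    if not residues:
        return None, 0.0
    (modal, count), = Counter(residues).most_common(1)
    return modal, count / len(residues)


def find_discriminating_positions(
    aln: LabelledAlignment,
    threshold: float = 1.0,
    gap_policy: str = "strict",
    annotations: dict[int, str] | None = None,
    near_window: int = 2,
) -> list[DiscriminatingPosition]:
    """Columns conserved within each family but differing between families.

    A column qualifies when each family's modal residue reaches `threshold`
    (a fraction in (0.5, 1.0]) and the two modal residues differ.  With an
    annotation map {reference position: site label}, hits within
    `near_window` positions of an annotated residue are tagged.
    Deterministic; sorted by alignment column.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0.5, 1.0], got {threshold}")
    fams = aln.families
    if len(fams) != 2:
        raise ValidationError(f"discrimination analysis needs exactly 2 families, got {fams}")
    fam_a, fam_b = fams
    rows_a, rows_b = aln.family(fam_a), aln.family(fam_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValidationError("each family needs >= 2 sequences")
    hits = []
    for col in range(aln.length):
        modal_a, cons_a = _column_consensus([s[col] for s in rows_a], gap_policy)
        modal_b, cons_b = _column_consensus([s[col] for s in rows_b], gap_policy)
        if modal_a is None or modal_b is None:
            continue
        if modal_a == modal_b or cons_a < threshold or cons_b < threshold:
            continue
        refpos = aln.reference_numbering(col)
        near = None
        if annotations and refpos is not None:
            for site, label in sorted(annotations.items()):
                if abs(site - refpos) <= near_window:
                    near = label
                    break
        hits.append(
            DiscriminatingPosition(
                column=col,
                reference_position=refpos,
                consensus_a=modal_a,
                consensus_b=modal_b,
                conservation_a=cons_a,
                conservation_b=cons_b,
                near_site=near,
            )
        )
    return hits


_BASIC = set("KR")
_ACIDIC = set("DE")
_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def nterm_charge(sequence: str, window: int = 27, his_charge: int = 0) -> int:
    """Formal charge of the first `window` residues (+1 K/R, −1 D/E).

    Histidine counts `his_charge` (0 by default, +1 to treat it as
    protonated).  The default 27-residue window matches the unstructured
    N-terminal region preceding the globular cap-binding domain.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    if window > len(sequence):
        raise ValidationError(f"window {window} exceeds sequence length {len(sequence)}")
    prefix = sequence[:window].upper()
    bad = set(prefix) - _RESIDUES
    if bad:
        raise ValidationError(f"non-residue characters in sequence: {sorted(bad)}")
    charge = 0
    for aa in prefix:
        if aa in _BASIC:
            charge += 1
        elif aa in _ACIDIC:
            charge -= 1
        elif aa == "H":
            charge += his_charge
    return charge


def map_numbering(position: int, offset: int) -> int:
    """Translate a residue number between conventions differing by `offset`."""
    result = position + offset
    if result < 1:
        raise ValidationError(f"mapped position {result} < 1")
    return result


def load_numbering_offsets(path=None) -> dict[str, int]:
    """Offsets that translate other conventions into heIF4E1a numbering."""
    if path is None:
        text = resources.files("capbind").joinpath("data/numbering_offsets.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return {k: int(v) for k, v in yaml.safe_load(text)["to_heIF4E1a"].items()}


def load_site_annotations(path=None) -> dict[int, str]:
    """Functional-site annotation keyed to heIF4E1a residue numbering."""
    if path is None:
        text = resources.files("capbind").joinpath("data/site_annotations.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return {int(k): str(v) for k, v in yaml.safe_load(text)["sites"].items()}
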