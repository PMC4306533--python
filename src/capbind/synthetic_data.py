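"""Synthetic titration curves, replicate studies, and toy paralog alignments.

The generator emulates the design of a cap-binding fluorescence titration:
0.1–0.2 μM protein, total ligand log-spaced from 2 μM up to 5 mM above a
zero point, homoscedastic Gaussian noise scaled to the zero-ligand signal,
and an optional linear apo-protein signal drift (10–25% over the run) of the
kind that motivates stabilizing marginal proteins before titrating.  It also
plants family-discriminating columns in toy two-family alignments for the
comparative-sequence stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_model import (
    BindingParameters,
    TitrationCurve,
    TitrationPoint,
    ValidationError,
    model_fluorescence,
)


def default_ligand_schedule(n_points: int = 25, lo: float = 0.02, hi: float = 50.0):
    """Zero point plus (n_points−1) log-spaced in-cuvette totals (μM).

    Titrations of this design add aliquots of cap stocks spanning ~2 μM to
    5 mM; the resulting *in-cuvette* totals must bracket the binding
    transition of a 0.1–0.2 μM protein (dissociation constants down to
    ~15 nM), so the default runs from 0.02 μM to 50 μM.  A schedule whose
    first nonzero point already saturates the protein leaves the
    association constant unidentifiable.
    """
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_points - 1)])


@dataclass
class SimulationDesign:
    """Design of one simulated titration.

    ligand_schedule   total-ligand concentrations (μM), non-decreasing, first 0
    protein_nominal   nominal protein concentration (μM)
    addition_volumes  optional cumulative volumes (μL) per point
    noise_sd_frac     Gaussian noise SD as a fraction of f0
    drift_total_frac  fraction of f0 lost linearly (in point index) over the
                      run at zero ligand; 0.10–0.25 emulates an unstable apo
                      protein
    seed              RNG seed (identical seed ⇒ bit-identical curves)
    """

    ligand_schedule: np.ndarray = field(default_factory=default_ligand_schedule)
    protein_nominal: float = 0.1
    addition_volumes: np.ndarray | None = None
    noise_sd_frac: float = 0.01
    drift_total_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sched = np.asarray(self.ligand_schedule, dtype=float)
        if self.noise_sd_frac < 0:
            raise ValidationError("noise_sd_frac must be >= 0")
        if not 0 <= self.drift_total_frac < 1:
            raise ValidationError("drift_total_frac must be in [0, 1)")
        if sched[0] != 0 or np.any(np.diff(sched) < 0):
            raise ValidationError("ligand_schedule must be non-decreasing, starting at 0")
        self.ligand_schedule = sched


def simulate_titration(
    truth: BindingParameters, design: SimulationDesign, protein_id: str = "sim", ligand: str = "sim",
    buffer_tag: str = "standard",
) -> TitrationCurve:
    """One synthetic curve: model signal × linear drift + Gaussian noise."""
    truth.validate()
    rng = np.random.default_rng(design.seed)
    lig = design.ligand_schedule
    n = len(lig)
    clean = np.asarray(model_fluorescence(truth, lig), dtype=float)
    if n > 1 and design.drift_total_frac > 0:
        drift = 1.0 - design.drift_total_frac * np.arange(n) / (n - 1)
        clean = clean * drift
    noisy = clean + rng.normal(0.0, design.noise_sd_frac * truth.f0, size=n) if design.noise_sd_frac > 0 else clean
    vols = design.addition_volumes
    points = [
        TitrationPoint(
            float(lig[i]),
            float(noisy[i]),
            volume=None if vols is None else float(vols[i]),
        )
        for i in range(n)
    ]
    return TitrationCurve(
        protein_id=protein_id, ligand=ligand, points=points, buffer_tag=buffer_tag
    )


def default_truth(kas: float, protein_nominal: float = 0.1) -> BindingParameters:
    """Representative fluorescence coefficients for a simulated protein."""
    return BindingParameters(
        kas=kas, p0_act=protein_nominal, f0=1000.0, delta_f=5000.0, f_lig=1.5
    )


@dataclass
class StudyBundle:
    """Simulated replicate study: curves plus a ground-truth manifest."""

    curves: list[TitrationCurve]
    manifest: pd.DataFrame


def simulate_replicate_study(
    cells: list[tuple[str, str, float]],
    replicates_per_cell: int,
    design: SimulationDesign,
) -> StudyBundle:
    """Curves for each (protein, ligand, true kas) cell × replicate.

    Per-curve seeds are spawned deterministically from design.seed, so the
    whole bundle is reproducible from a single integer.
    """
    if not cells:
        raise ValidationError("cell list must be non-empty")
    if replicates_per_cell < 1:
        raise ValidationError("replicates_per_cell must be >= 1")
    curves = []
    manifest_rows = []
    ss = np.random.SeedSequence(design.seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(cells) * replicates_per_cell)]
    i = 0
    for protein, ligand, kas_true in cells:
        truth = default_truth(kas_true, design.protein_nominal)
        manifest_rows.append(
            {
                "protein": protein,
                "ligand": ligand,
                "kas_true": kas_true,
                "p0_act": truth.p0_act,
                "f0": truth.f0,
                "delta_f": truth.delta_f,
                "f_lig": truth.f_lig,
                "replicates": replicates_per_cell,
            }
        )
        for _ in range(replicates_per_cell):
            d = SimulationDesign(
                ligand_schedule=design.ligand_schedule.copy(),
                protein_nominal=design.protein_nominal,
                addition_volumes=design.addition_volumes,
                noise_sd_frac=design.noise_sd_frac,
                drift_total_frac=design.drift_total_frac,
                seed=child_seeds[i],
            )
            curves.append(simulate_titration(truth, d, protein_id=protein, ligand=ligand))
            i += 1
    return StudyBundle(curves=curves, manifest=pd.DataFrame(manifest_rows))


# --- toy paralog alignments -------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_family_alignment(
    n_per_family: int = 4,
    length: int = 60,
    n_discriminating: int = 5,
    within_family_noise: float = 0.0,
    seed: int = 0,
):
    """Toy two-family alignment with planted discriminating columns.

    Returns (sequences, planted_columns) where sequences is a list of
    (id, family, aligned_str) with families "A" and "B", and planted_columns
    are 0-based indices at which the two families carry different conserved
    residues.  within_family_noise is the per-site probability of a random
    substitution within a family (degrades conservation).
    """
    if n_discriminating > length:
        raise ValidationError("cannot plant more discriminating columns than length")
    rng = np.random.default_rng(seed)
    backbone = rng.choice(_AA, size=length)
    planted = np.sort(rng.choice(length, size=n_discriminating, replace=False))
    consensus = {"A": backbone.copy(), "B": backbone.copy()}
    for col in planted:
        a, b = rng.choice(_AA, size=2, replace=False)
        consensus["A"][col] = a
        consensus["B"][col] = b
    sequences = []
    for fam in ("A", "B"):
        for i in range(n_per_family):
            seq = consensus[fam].copy()
            if within_family_noise > 0:
                mask = rng.random(length) < within_family_noise
                seq[mask] = rng.choice(_AA, size=int(mask.sum()))
            sequences.append((f"{fam}{i + 1}", fam, "".join(seq)))
    return sequences, [int(c) for c in planted]
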