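"""Single-site equilibrium binding with ligand depletion and its fluorescence observable.

At the protein concentrations used in cap-binding titrations (~0.1 μM) the
bound ligand is not a negligible fraction of total ligand at the low end of
the titration, so the free-ligand concentration cannot be approximated by the
total: the complex concentration is the root of a quadratic in [PL]
(mass-action with conservation of both species).  The measured signal is the
sum of emission from apo protein (active + inactive), the protein–cap complex
(quenched) and free cap analogue, which dominates at millimolar ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a model invariant."""


@dataclass
class BindingParameters:
    """Parameters of the fluorescence titration model.

    kas       association constant, μM⁻¹
    p0_act    total *active* protein concentration, μM
    f0        fluorescence of the protein solution at zero ligand (a.u.);
              absorbs apo-active and inactive protein emission, which are not
              separately identifiable from a titration
    delta_f   quench amplitude per μM of complex (f_apo − f_complex), a.u./μM
    f_lig     fluorescence efficiency of free ligand, a.u./μM
    """

    kas: float
    p0_act: float
    f0: float
    delta_f: float
    f_lig: float

    def validate(self) -> "BindingParameters":
        if self.kas <= 0:
            raise ValidationError(f"kas must be positive, got {self.kas}")
        if self.p0_act < 0:
            raise ValidationError(f"p0_act must be non-negative, got {self.p0_act}")
        if self.delta_f < 0:
            raise ValidationError(f"delta_f must be non-negative, got {self.delta_f}")
        if self.f_lig < 0:
            raise ValidationError(f"f_lig must be non-negative, got {self.f_lig}")
        return self


@dataclass
class TitrationPoint:
    """One titration point: total added ligand and the observed signal.

    volume (cumulative sample volume, μL) and the absorbances at the
    excitation/emission wavelengths are optional; when absent the
    corresponding correction is the identity.
    """

    ligand_total: float
    fluorescence_raw: float
    volume: float | None = None
    a_ex: float | None = None
    a_em: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise ValidationError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if self.fluorescence_raw < 0:
            raise ValidationError(
                f"fluorescence_raw must be >= 0, got {self.fluorescence_raw}"
            )
        for name in ("a_ex", "a_em"):
            a = getattr(self, name)
            if a is not None and a < 0:
                raise ValidationError(f"{name} must be >= 0, got {a}")


@dataclass
class TitrationCurve:
    """One titration experiment with its metadata."""

    protein_id: str
    ligand: str
    points: list[TitrationPoint]
    temperature: float = 293.15
    buffer_tag: str = "standard"
    excitation_nm: float = 280.0
    observation_nm: float = 337.0

    def __post_init__(self) -> None:
        if len(self.points) < 6:
            raise ValidationError(
                f"titration needs >= 6 points, got {len(self.points)}"
            )
        lig = [p.ligand_total for p in self.points]
        if lig[0] != 0:
            raise ValidationError("first titration point must have ligand_total = 0")
        if any(b < a for a, b in zip(lig, lig[1:])):
            raise ValidationError("ligand_total must be non-decreasing across points")

    @property
    def ligand_totals(self) -> np.ndarray:
        return np.array([p.ligand_total for p in self.points], dtype=float)

    @property
    def fluorescence(self) -> np.ndarray:
        return np.array([p.fluorescence_raw for p in self.points], dtype=float)


def complex_concentration(kas, p0_act, ligand_total):
    """Equilibrium complex concentration [PL] (μM) under ligand depletion.

    Root of K_as·([P0]−[PL])·([L0]−[PL]) = [PL] chosen in
    [0, min(p0, L0)].  Evaluated in the cancellation-free form
    2ab/(s + sqrt(s² − 4ab)) with s = p0 + L0 + 1/K_as, which stays accurate
    up to the stoichiometric regime (kas → 1e9 μM⁻¹).  Accepts scalars or
    arrays (broadcast).
    """
    kas = np.asarray(kas, dtype=float)
    p0 = np.asarray(p0_act, dtype=float)
    l0 = np.asarray(ligand_total, dtype=float)
    if np.any(kas <= 0):
        raise ValidationError("kas must be positive")
    if np.any(p0 < 0) or np.any(l0 < 0):
        raise ValidationError("concentrations must be non-negative")
    s = p0 + l0 + 1.0 / kas
    ab = p0 * l0
    disc = s * s - 4.0 * ab
    # disc >= (p0 - l0)^2 analytically; clip guards rounding at exact equality
    out = 2.0 * ab / (s + np.sqrt(np.maximum(disc, 0.0)))
    if out.ndim == 0:
        return float(out)
    return out


def model_fluorescence(params: BindingParameters, ligand_total):
    """Predicted fluorescence F(L0) = f0 − Δf·[PL] + f_L·([L0] − [PL])."""
    pl = complex_concentration(params.kas, params.p0_act, ligand_total)
    return params.f0 - params.delta_f * pl + params.f_lig * (
        np.asarray(ligand_total, dtype=float) - pl
    )


def correct_intensities(point: TitrationPoint, reference_volume: float | None = None):
    """Dilution and inner-filter corrected intensity for one point.

    F_corr = F_raw × (V/V_ref) × 10^((A_ex + A_em)/2).  The half-path
    inner-filter form is the standard right-angle-geometry correction.
    Missing optional fields behave as V = V_ref and A = 0.
    """
    factor = 1.0
    if point.volume is not None:
        if reference_volume is None or reference_volume <= 0:
            raise ValidationError("reference_volume must be positive when volumes are present")
        if point.volume < reference_volume:
            raise ValidationError(
                f"volume {point.volume} < reference {reference_volume}: "
                "titrations only add volume"
            )
        factor *= point.volume / reference_volume
    a_ex = point.a_ex or 0.0
    a_em = point.a_em or 0.0
    factor *= 10.0 ** ((a_ex + a_em) / 2.0)
    return point.fluorescence_raw * factor


def correct_curve(curve: TitrationCurve) -> TitrationCurve:
    """Apply per-point corrections to a whole curve.

    The first point's volume (when recorded) is the dilution reference.
    Returns a new curve whose raw intensities are the corrected ones and
    whose optional fields are cleared (already applied).
    """
    ref = curve.points[0].volume
    pts = [
        TitrationPoint(p.ligand_total, correct_intensities(p, ref))
        for p in curve.points
    ]
    return TitrationCurve(
        protein_id=curve.protein_id,
        ligand=curve.ligand,
        points=pts,
        temperature=curve.temperature,
        buffer_tag=curve.buffer_tag,
        excitation_nm=curve.excitation_nm,
        observation_nm=curve.observation_nm,
    )


# --- titration CSV I/O ------------------------------------------------------
#
# Format: optional leading comment block of "# key: value" lines carrying the
# curve metadata, then a mandatory header row.  Columns: ligand_total_uM,
# fluorescence, and optionally volume_uL, a_ex, a_em.

_META_KEYS = {
    "protein_id": str,
    "ligand": str,
    "temperature": float,
    "buffer_tag": str,
    "excitation_nm": float,
    "observation_nm": float,
}


def write_titration_csv(curve: TitrationCurve, path) -> None:
    rows = []
    for p in curve.points:
        rows.append(
            {
                "ligand_total_uM": p.ligand_total,
                "fluorescence": p.fluorescence_raw,
                "volume_uL": p.volume,
                "a_ex": p.a_ex,
                "a_em": p.a_em,
            }
        )
    df = pd.DataFrame(rows)
    # drop all-empty optional columns
    for col in ("volume_uL", "a_ex", "a_em"):
        if df[col].isna().all():
            df = df.drop(columns=col)
    with open(path, "w", encoding="utf-8") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}: {getattr(curve, key)}\n")
        df.to_csv(fh, index=False)


def read_titration_csv(path) -> TitrationCurve:
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("#").partition(":")
            key = key.strip()
            if key in _META_KEYS:
                meta[key] = _META_KEYS[key](value.strip())
        else:
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if "ligand_total_uM" not in df.columns or "fluorescence" not in df.columns:
        raise ValidationError(
            "titration CSV needs columns ligand_total_uM and fluorescence"
        )

    def opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    points = [
        TitrationPoint(
            float(row["ligand_total_uM"]),
            float(row["fluorescence"]),
            volume=opt(row, "volume_uL"),
            a_ex=opt(row, "a_ex"),
            a_em=opt(row, "a_em"),
        )
        for _, row in df.iterrows()
    ]
    return TitrationCurve(
        protein_id=meta.get("protein_id", "unknown"),
        ligand=meta.get("ligand", "unknown"),
        points=points,
        temperature=meta.get("temperature", 293.15),
        buffer_tag=meta.get("buffer_tag", "standard"),
        excitation_nm=meta.get("excitation_nm", 280.0),
        observation_nm=meta.get("observation_nm", 337.0),
    )
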