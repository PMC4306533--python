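"""Association-constant estimation from titration curves and replicate pooling.

One curve gives a nonlinear least-squares estimate of
{K_as, [P0_act], f0, Δf, f_L}; independent replicates of the same
protein×ligand cell are pooled by inverse-variance weighting, with the
pooled standard error sqrt(1/Σ(1/σ_i²)).

The optimizer is trust-region-reflective least squares with an analytic
Jacobian (the complex concentration is differentiated implicitly through the
mass-action equation) and physical bounds.  K_as is multi-started on a log
grid because tight binders place the optimum in a shallow valley where a
single bad start can stall.  Standard errors come from the curvature of the
objective at the optimum scaled by the residual variance; the covariance is
built from an SVD of the Jacobian that keeps *all* numerically nonzero
directions — the K_as/[P0_act]/Δf correlation is strong in weak-binding
regimes, and truncating it silently underreports the uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .binding_model import (
    BindingParameters,
    TitrationCurve,
    ValidationError,
    correct_curve,
)

PARAM_NAMES = ("kas", "p0_act", "f0", "delta_f", "f_lig")


class NonIdentifiableError(ValueError):
    """The data cannot constrain the model (e.g. no quench signal)."""


@dataclass
class FitSettings:
    """Configuration for :func:`fit_titration`.

    protein_nominal   nominal total protein concentration (μM); bounds p0_act
                      to (0, 2×nominal] and seeds its start value
    kas_starts        multi-start grid for the association constant (μM⁻¹)
    apply_corrections run dilution/inner-filter corrections before fitting
    fix_p0            pin p0_act at the nominal value instead of fitting it
    seed              seed for optional multi-start jitter (the only source
                      of randomness; None and jitter_frac=0 ⇒ deterministic)
    """

    protein_nominal: float = 0.1
    kas_starts: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    apply_corrections: bool = False
    fix_p0: bool = False
    seed: int | None = None
    jitter_frac: float = 0.0
    xtol: float = 1e-12
    ftol: float = 1e-12


@dataclass
class FitResult:
    params: BindingParameters
    se: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    residuals: np.ndarray

    @property
    def kas(self) -> float:
        return self.params.kas

    @property
    def kas_se(self) -> float:
        return self.se["kas"]


@dataclass
class AffinityRecord:
    """Inverse-variance-pooled K_as ± SE for one protein×ligand×buffer cell."""

    protein_id: str
    ligand: str
    buffer_tag: str
    kas: float
    kas_se: float
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.kas <= 0:
            raise ValidationError(f"kas must be positive, got {self.kas}")
        if self.kas_se < 0:
            raise ValidationError(f"kas_se must be >= 0, got {self.kas_se}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def _complex_and_grads(kas, p0, lig):
    """[PL] and its partials wrt kas and p0 (implicit differentiation)."""
    s = p0 + lig + 1.0 / kas
    ab = p0 * lig
    x = 2.0 * ab / (s + np.sqrt(np.maximum(s * s - 4.0 * ab, 0.0)))
    denom = 1.0 + kas * (p0 - x) + kas * (lig - x)
    dx_dkas = (p0 - x) * (lig - x) / denom
    dx_dp0 = kas * (lig - x) / denom
    return x, dx_dkas, dx_dp0


def _initial_guesses(lig: np.ndarray, flu: np.ndarray, settings: FitSettings):
    """Physics-informed starting values (multi-start only over kas)."""
    f0 = flu[0]
    if lig[-1] > lig[-2]:
        f_lig = max((flu[-1] - flu[-2]) / (lig[-1] - lig[-2]), 0.0)
    else:
        f_lig = 0.0
    plateau = np.min(flu - f_lig * lig)
    delta_f = max((f0 - plateau) / settings.protein_nominal, 1e-6)
    return f0, delta_f, f_lig


def fit_titration(curve: TitrationCurve, settings: FitSettings | None = None) -> FitResult:
    """Estimate binding parameters for one titration curve."""
    settings = settings or FitSettings()
    if settings.apply_corrections:
        curve = correct_curve(curve)
    lig = curve.ligand_totals
    flu = curve.fluorescence
    if len(lig) < 6:
        raise ValidationError(f"titration needs >= 6 points, got {len(lig)}")
    if np.ptp(flu) == 0:
        raise NonIdentifiableError(
            "all fluorescence values are equal: delta_f (quench amplitude) "
            "is not identifiable from a flat curve"
        )

    f0_init, delta_f_init, f_lig_init = _initial_guesses(lig, flu, settings)
    fit_p0 = not settings.fix_p0
    p0_fixed = settings.protein_nominal

    if fit_p0:
        lower = np.array([1e-9, 1e-12, 0.0, 0.0, 0.0])
        upper = np.array([1e9, 2.0 * settings.protein_nominal, np.inf, np.inf, np.inf])
    else:
        lower = np.array([1e-9, 0.0, 0.0, 0.0])
        upper = np.array([1e9, np.inf, np.inf, np.inf])

    def unpack(theta):
        if fit_p0:
            kas, p0, f0, delta_f, f_lig = theta
        else:
            kas, f0, delta_f, f_lig = theta
            p0 = p0_fixed
        return kas, p0, f0, delta_f, f_lig

    def residual(theta):
        kas, p0, f0, delta_f, f_lig = unpack(theta)
        x, _, _ = _complex_and_grads(kas, p0, lig)
        return f0 - delta_f * x + f_lig * (lig - x) - flu

    def jacobian(theta):
        kas, p0, f0, delta_f, f_lig = unpack(theta)
        x, dx_dkas, dx_dp0 = _complex_and_grads(kas, p0, lig)
        c = -delta_f - f_lig
        cols = [c * dx_dkas]
        if fit_p0:
            cols.append(c * dx_dp0)
        cols += [np.ones_like(lig), -x, lig - x]
        return np.column_stack(cols)

    rng = (
        np.random.default_rng(settings.seed)
        if settings.seed is not None and settings.jitter_frac > 0
        else None
    )
    best = None
    for kas0 in settings.kas_starts:
        jit = 1.0 + settings.jitter_frac * rng.standard_normal() if rng is not None else 1.0
        start = [kas0 * jit]
        if fit_p0:
            start.append(settings.protein_nominal)
        start += [f0_init, delta_f_init, f_lig_init]
        try:
            out = least_squares(
                residual,
                np.clip(start, lower, upper),
                jac=jacobian,
                bounds=(lower, upper),
                x_scale="jac",
                xtol=settings.xtol,
                ftol=settings.ftol,
                gtol=None,
            )
        except Exception:
            continue
        if best is None or out.cost < best.cost:
            best = out
    if best is None:
        raise NonIdentifiableError("optimizer failed from every start")

    kas, p0, f0, delta_f, f_lig = unpack(best.x)
    params = BindingParameters(kas=kas, p0_act=p0, f0=f0, delta_f=delta_f, f_lig=f_lig)

    n, p = len(lig), len(best.x)
    sigma2 = 2.0 * best.cost / max(n - p, 1)
    jac = jacobian(best.x)
    _, sv, vt = np.linalg.svd(jac, full_matrices=False)
    thresh = np.finfo(float).eps * max(jac.shape) * sv[0]
    keep = sv > thresh
    sv, vt = sv[keep], vt[keep]
    cov = (vt.T / sv**2) @ vt * sigma2
    diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if fit_p0:
        se = dict(zip(PARAM_NAMES, diag))
    else:
        se = {"kas": diag[0], "p0_act": 0.0, "f0": diag[1], "delta_f": diag[2], "f_lig": diag[3]}
    se = {k: float(v) for k, v in se.items()}

    res = residual(best.x)
    return FitResult(
        params=params,
        se=se,
        rss=float(np.sum(res**2)),
        n_points=n,
        converged=bool(best.status > 0),
        residuals=res,
    )


def weighted_average(fits: list[tuple[float, float]]) -> tuple[float, float]:
    """Inverse-variance pooled (kas, se) across replicate fits.

    Weights are 1/σ_i²; pooled se = sqrt(1/Σ(1/σ_i²)).
    """
    if not fits:
        raise ValidationError("no replicate estimates to pool")
    k = np.array([f[0] for f in fits], dtype=float)
    s = np.array([f[1] for f in fits], dtype=float)
    if np.any(s <= 0):
        raise ValidationError(
            "every replicate needs a positive standard error; exact replicates "
            "with se = 0 cannot be weighted (consider jittering or dropping them)"
        )
    w = 1.0 / s**2
    return float(np.sum(w * k) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))


def aggregate_fits(
    fits: list[FitResult],
    protein_id: str,
    ligand: str,
    buffer_tag: str = "standard",
) -> AffinityRecord:
    """Pool replicate FitResults for one cell into an AffinityRecord."""
    kas, se = weighted_average([(f.kas, f.kas_se) for f in fits])
    return AffinityRecord(
        protein_id=protein_id,
        ligand=ligand,
        buffer_tag=buffer_tag,
        kas=kas,
        kas_se=se,
        n_replicates=len(fits),
    )
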