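"""Recurrent shunting dynamics of the full model, with lesionable feedback.

The curved-contour field is a static (feedforward) function of the display's
edge map.  The convex and teardrop fields evolve by exponential-Euler
updates of shunting membrane equations

    dx/dt = -A*x + (B - x)*E - (D + x)*I

(each step applies the exact solution of the ODE with the drives frozen),
whose multiplicative gating keeps every activity inside [-D, B] for any
nonnegative drives E and I and any step size.  For convex cells E collects the gated annulus
drive and (when the teardrop pathway is intact) the spread excitatory
closure feedback; I collects cross-scale competition, the coarse-to-fine
recurrent inhibition (when that pathway is intact) and inhibitory closure
feedback.  Teardrop cells relax toward their ramp drive with the same decay.
Updates are synchronous: all drives are computed from the state at time t,
then both layers step together, so the result is independent of any
within-step ordering.

All dynamical constants live in :class:`SimParams`.  The governing equations
follow the standard shunting form with A = B = 1 and D = 0; every gain and
threshold is exposed so alternative constants can be substituted wholesale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import ait, pit, v4
from .stimuli import VisualDisplay, compute_edge_map


@dataclass(frozen=True)
class LesionConfig:
    """Which feedback pathways are enabled.

    The four combinations name the lesion conditions: Feedback-Intact
    (both True), Convex-Only Feedback, Teardrop-Only Feedback, No-Feedback.
    """

    convex_recurrent_on: bool = True
    teardrop_feedback_on: bool = True

    @property
    def name(self) -> str:
        return {
            (True, True): "intact",
            (True, False): "convex_only",
            (False, True): "teardrop_only",
            (False, False): "none",
        }[(self.convex_recurrent_on, self.teardrop_feedback_on)]


LESION_CONDITIONS = {
    "intact": LesionConfig(True, True),
    "convex_only": LesionConfig(True, False),
    "teardrop_only": LesionConfig(False, True),
    "none": LesionConfig(False, False),
}


@dataclass(frozen=True)
class SimParams:
    """Dynamical constants of the model.

    Shunting constants ``decay`` (A), ``ceiling`` (B) and ``floor`` (D);
    Euler step ``dt``; pathway gains; and the static thresholds of the
    curved (theta_c), teardrop (theta_t) and closure-feedback (theta_f)
    stages.  ``seed`` is recorded with every run for provenance; the model
    itself is deterministic.
    """

    decay: float = 1.0
    ceiling: float = 1.0
    floor: float = 0.0
    dt: float = 0.15
    n_steps: int = 400
    convergence_tol: float = 1e-4
    # pathway gains
    ff_gain: float = 18.0            # annulus drive -> convex excitation
    comp_gain: float = 16.0          # cross-scale competition
    rec_gain: float = 5.0            # convex recurrent inhibition
    rec_kappa: float = 1.5           # shared-boundary cancellation strength
    td_gain: float = 6.0             # convex ramps -> teardrop drive
    fb_exc_gain: float = 2.0         # positive closure feedback boost
    fb_inh_gain: float = 1.5         # negative closure feedback, subtractive
    fb_residual: float = 0.05        # fraction of drive surviving full suppression
    # stage thresholds / shapes
    theta_c: float = 0.4
    theta_t: float = 0.25
    theta_f: float = 2.6
    g_half: float = 0.4
    g_pow: float = 4.0
    fb_spread_sigma: float = 1.5
    jitter_floor: float = 1.8
    cover_pow: float = 3.0
    jitter_leak: float = 0.0
    ring_sigma: float = 1.2
    td_blur: float = 0.8
    td_leak: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.decay <= 0 or self.ceiling <= 0 or self.dt <= 0:
            raise ValueError("decay, ceiling and dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class ModelState:
    """All layer activities at one timestep."""

    curved: np.ndarray     # (H, W, n_arcs, n_scales), static per display
    convex: np.ndarray     # (H, W, n_scales)
    teardrop: np.ndarray   # (H, W, 8)
    maturity: float = 0.0  # latched readiness of the closure verdict, in [0, 1)
    t: int = 0


@dataclass
class Trajectory:
    """Result of :func:`run`: final state plus recorded history."""

    display: VisualDisplay
    lesion: LesionConfig
    params: SimParams
    final: ModelState
    converged: bool
    n_steps_run: int
    teardrop_peak: float = 0.0     # largest teardrop activity over the run
    convex_history: np.ndarray | None = None   # (T, H, W, n_scales)

    def time_course(self, position: tuple[int, int], scale: int) -> np.ndarray:
        return time_course(self, position, scale)


class _Precomputed:
    """Static per-display quantities reused on every step."""

    def __init__(self, display: VisualDisplay, params: SimParams,
                 bank: v4.ArcBank, annulus: pit.AnnulusParams,
                 geom: ait.TeardropGeometry):
        self.bank = bank
        self.annulus = annulus
        self.geom = geom
        self.kernels = pit.PitKernels(annulus)
        edge_map = compute_edge_map(display)
        self.edge_total = edge_map.total
        self.curved = v4.curved_response(edge_map, bank)
        self.drive, self.gate = pit.annulus_drive(self.curved, annulus)
        self.edge_ring = [self.kernels.ringpool(self.edge_total, s)
                          for s in range(len(annulus.radii))]


def _default_stage_params(params: SimParams) -> tuple[v4.ArcBank,
                                                      pit.AnnulusParams,
                                                      ait.TeardropGeometry]:
    bank = v4.build_arc_bank(threshold=params.theta_c,
                             ring_sigma=params.ring_sigma)
    annulus = pit.AnnulusParams(jitter_floor=params.jitter_floor,
                                cover_pow=params.cover_pow,
                                jitter_leak=params.jitter_leak)
    geom = ait.TeardropGeometry(threshold=params.theta_t,
                                blur_sigma=params.td_blur,
                                scale_leak=params.td_leak)
    return bank, annulus, geom


def step(state: ModelState, pre: _Precomputed, lesion: LesionConfig,
         params: SimParams) -> ModelState:
    """One synchronous update of both dynamical layers."""
    A, B, D, dt = params.decay, params.ceiling, params.floor, params.dt
    x, T = state.convex, state.teardrop

    ff = pre.drive
    fb_boost = None
    I = params.comp_gain * pit.cross_scale_competition(x)
    td_ramp = ait.teardrop_drive(x, pre.geom)

    if lesion.convex_recurrent_on:
        I = I + params.rec_gain * pit.convex_recurrent_inhibition(
            x, pre.edge_total, pre.kernels, kappa=params.rec_kappa,
            edge_ring=pre.edge_ring)

    if lesion.teardrop_feedback_on:
        F = ait.teardrop_feedback(T, pre.geom, g_half=params.g_half,
                                  theta_f=params.theta_f, g_pow=params.g_pow)
        # normalize both halves to [0, 1] so the feedback gains are
        # comparable across theta_f settings
        n_dirs = T.shape[-1]
        pos = np.maximum(F, 0.0) / (n_dirs - params.theta_f)
        neg = np.maximum(-F, 0.0) / params.theta_f
        # the closure verdict only applies once the teardrop layer has had
        # a chance to form: suppression is scaled by a global maturity
        # factor that saturates when any teardrop cell is decisively
        # active, and latches so the verdict cannot un-form and drive a
        # relaxation cycle.  Early in a run nothing is suppressed and the
        # feedforward sweep establishes candidate medial responses; once
        # closure evidence exists anywhere, absence of agreement counts
        # against a figure — the late-component character of interior
        # enhancement
        mature = max(state.maturity,
                     float(ait.sigmoid_agreement(T.max(), params.g_half,
                                                 params.g_pow)))
        # both halves are spread over a small neighbourhood: closure evidence
        # modulates the convex cells around the teardrop position
        exc = gaussian_filter(pos, params.fb_spread_sigma)
        inh = gaussian_filter(neg, params.fb_spread_sigma) * mature
        fb_boost = params.fb_exc_gain * exc[:, :, None]
        fb_sub = params.fb_inh_gain * inh[:, :, None]
    else:
        fb_sub = None

    # closure feedback is modulatory on the feedforward drive: the positive
    # half amplifies the annulus drive a cell already receives (it cannot
    # create activity at scales with no feedforward support) and the
    # negative half subtracts from it, down to a small residual fraction of
    # the drive — suppression is strong but does not completely abolish a
    # cell's feedforward response
    E = params.ff_gain * ff
    if fb_boost is not None:
        E_b = E * (1.0 + fb_boost)
        E = np.maximum(E_b - fb_sub, params.fb_residual * E_b)

    # exponential-Euler update: exact solution of the shunting ODE with the
    # drives frozen over the step.  x_new is a convex combination of x and
    # the instantaneous equilibrium (B*E - D*I)/(A + E + I), so activities
    # can never leave [-D, B] regardless of dt or gain settings.
    rate = A + E + I
    x_eq = (B * E - D * I) / rate
    x_new = x_eq + (x - x_eq) * np.exp(-rate * dt)

    td_drive = params.td_gain * td_ramp
    rate_t = A + td_drive
    t_eq = B * td_drive / rate_t
    T_new = t_eq + (T - t_eq) * np.exp(-rate_t * dt)

    lo, hi = -D - 1e-6, B + 1e-6
    for arr, label in ((x_new, "convex"), (T_new, "teardrop")):
        if arr.min() < lo - 1e-3 or arr.max() > hi + 1e-3:
            raise FloatingPointError(
                f"{label} activity left the shunting bounds "
                f"[{-D}, {B}]: range [{arr.min():.4f}, {arr.max():.4f}]")
    np.clip(x_new, -D, B, out=x_new)
    np.clip(T_new, -D, B, out=T_new)
    new_maturity = mature if lesion.teardrop_feedback_on else state.maturity
    return ModelState(curved=state.curved, convex=x_new, teardrop=T_new,
                      maturity=new_maturity, t=state.t + 1)


#: static per-display precomputations are expensive (the curved-contour
#: convolutions); cache a handful so lesion conditions of the same display
#: share them
_PRE_CACHE: dict = {}
_PRE_CACHE_MAX = 16


def _static_key(display: VisualDisplay, params: SimParams) -> tuple:
    import hashlib
    mask_h = hashlib.sha1(display.figure_mask.tobytes()).hexdigest()
    stat = (params.theta_c, params.theta_t, params.ring_sigma,
            params.jitter_floor, params.cover_pow, params.jitter_leak,
            params.td_blur, params.td_leak)
    return (mask_h, display.params.get("figure_present", True), stat)


def run(display: VisualDisplay, lesion: LesionConfig = LesionConfig(),
        params: SimParams = SimParams(), record_history: bool = False,
        bank: v4.ArcBank | None = None) -> Trajectory:
    """Integrate the model on one display until convergence or ``n_steps``.

    Convergence is declared when the largest absolute per-step change of
    any convex activity falls below ``params.convergence_tol``.  The run is
    deterministic: identical inputs reproduce the trajectory bit-exactly.
    """
    key = _static_key(display, params) if bank is None else None
    if key is not None and key in _PRE_CACHE:
        pre = _PRE_CACHE[key]
        annulus, geom = pre.annulus, pre.geom
    else:
        if bank is None:
            bank, annulus, geom = _default_stage_params(params)
        else:
            _, annulus, geom = _default_stage_params(params)
        pre = _Precomputed(display, params, bank, annulus, geom)
        if key is not None:
            if len(_PRE_CACHE) >= _PRE_CACHE_MAX:
                _PRE_CACHE.pop(next(iter(_PRE_CACHE)))
            _PRE_CACHE[key] = pre
    h, w = display.shape
    n_scales = len(annulus.radii)
    state = ModelState(
        curved=pre.curved.activity,
        convex=np.zeros((h, w, n_scales)),
        teardrop=np.zeros((h, w, len(v4.DIRECTIONS))),
    )
    history = [state.convex.copy()] if record_history else None
    converged = False
    teardrop_peak = 0.0
    for _ in range(params.n_steps):
        new = step(state, pre, lesion, params)
        delta = np.abs(new.convex - state.convex).max()
        state = new
        teardrop_peak = max(teardrop_peak, float(state.teardrop.max()))
        if record_history:
            history.append(state.convex.copy())
        if delta < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"run on {display.name!r} did not converge in "
            f"{params.n_steps} steps", RuntimeWarning, stacklevel=2)
    return Trajectory(
        display=display, lesion=lesion, params=params, final=state,
        converged=converged, n_steps_run=state.t,
        teardrop_peak=teardrop_peak,
        convex_history=np.stack(history) if record_history else None)


def time_course(traj: Trajectory, position: tuple[int, int],
                scale: int) -> np.ndarray:
    """Per-step activity trace of one convex cell (requires history)."""
    if traj.convex_history is None:
        raise ValueError("run with record_history=True to extract time courses")
    y, x = position
    return traj.convex_history[:, y, x, scale]
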