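"""Equilibrium continuation in the pump parameter and bifurcation detection.

With the pump capacity held constant at a fraction ``p`` of baseline, the
closed 21-state system is autonomous and its equilibria form branches in
``p``.  The physiological (resting) branch terminates in a saddle-node
(limit point) as ``p`` is lowered — the loss of bistability that forces the
transit to the pathological state — while the pathological (depolarized)
branch loses stability through a Hopf bifurcation when ``p`` is raised above
baseline.

The extracellular compartment is already eliminated algebraically through the
conservation laws, removing the structural zero modes.  One quasi-neutral
direction remains: the overall scale of the vesicle-pool sector, whose
eigenvalue (|Re| ~ 1e-9/ms, a multi-hour timescale) sits below the noise of
finite-difference Jacobians.  Continuation and stability classification
therefore operate in a reduced system with the six pools frozen at their
baseline occupancies; all ions, gates and volumes stay free.  Jacobians are
central finite differences with per-state scaled steps (the state spans ~13
orders of magnitude).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core import NSTATE
from .simulate import HAVE_NUMBA, pack_params, rhs_autonomous
from ._fast import J_EVAL, rhs_fast

log = logging.getLogger(__name__)

__all__ = [
    "EquilibriumBranch",
    "BranchPoint",
    "BifurcationPoint",
    "NoEquilibrium",
    "find_equilibrium",
    "continue_branch",
    "detect_limit_point",
    "detect_hopf",
    "classify_bistability",
    "pathological_state",
]

RESIDUAL_TOL = 1e-10

#: all 21 states take part in the equilibrium solves
FREE = np.arange(21)
#: ion/gate/volume indices used to choose the local-parametrization
#: coordinate around folds (the vesicle pools vary wildly near the pool
#: sector's quasi-neutral degeneracy and make poor branch parameters)
CORE = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 19, 20])
#: eigenvalues with |Re| below this are treated as neutral when classifying
#: stability: the vesicle-pool scale mode sits at |Re| ~ 1e-9/ms (multi-hour
#: timescale), below finite-difference Jacobian noise
STABILITY_EPS = 1e-8


class NoEquilibrium(RuntimeError):
    """Newton failed to converge — used to detect branch termination."""


@dataclass
class BranchPoint:
    p: float
    y: np.ndarray
    eigvals: np.ndarray
    stable: bool


@dataclass
class EquilibriumBranch:
    """Ordered continuation output with stability flags."""

    points: list[BranchPoint] = field(default_factory=list)
    label: str = ""

    @property
    def p(self) -> np.ndarray:
        return np.array([pt.p for pt in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BifurcationPoint:
    kind: str               # "limit_point" | "hopf"
    p: float
    y: np.ndarray
    test_value: float = 0.0


# ---------------------------------------------------------------------------
# Newton machinery
# ---------------------------------------------------------------------------

def _scales(model) -> np.ndarray:
    return np.maximum(np.abs(model.y0), 1e-8)


def _row_scales(model, s: np.ndarray) -> np.ndarray:
    """Residual (row) scales from the baseline Jacobian: r_s = |J| s.

    The RHS rows span many orders of magnitude (pA-scale ion fluxes vs
    fmol/ms-scale vesicle kinetics); equilibrated Newton systems
    (D_r^-1 J D_c) keep the linear solves well conditioned.
    """
    rs = getattr(model, "_row_scales", None)
    if rs is None:
        j = _jac(model, model.y0, 1.0, s)
        rs = np.abs(j) @ s[FREE]
        rs = np.maximum(rs, 1e-6 * np.max(rs))
        model._row_scales = rs
    return rs


def _f(model, y, p):
    """Autonomous RHS at pump fraction p; None outside the admissible region."""
    if HAVE_NUMBA:
        P = getattr(model, "_packed", None)
        if P is None:
            P = pack_params(model, 0, p)
            model._packed = P
        P[J_EVAL] = p
        r = rhs_fast(0.0, y, P)
        if not np.all(np.isfinite(r)):
            return None
        return r
    try:  # pragma: no cover - reference fallback
        return rhs_autonomous(y, model.totals, model.geom, model.consts,
                              model.tp, model.vp, energy=p)
    except (ValueError, FloatingPointError):
        return None


def _jac(model, y, p, s) -> np.ndarray:
    """Central-difference Jacobian of the reduced (pool-frozen) system.

    Rows/columns span the FREE indices; steps are scaled per state.
    """
    nf = len(FREE)
    j = np.empty((nf, nf))
    h = 1.5e-8 * np.maximum(np.abs(y), 1e-3 * s)
    for col, k in enumerate(FREE):
        yp = y.copy(); yp[k] += h[k]
        ym = y.copy(); ym[k] -= h[k]
        fp, fm = _f(model, yp, p), _f(model, ym, p)
        if fp is None or fm is None:
            raise NoEquilibrium("state left the admissible region in Jacobian")
        j[:, col] = (fp[FREE] - fm[FREE]) / (2.0 * h[k])
    return j


def _dfdp(model, y, p) -> np.ndarray:
    hp = 1e-7 * max(abs(p), 0.1)
    fp, fm = _f(model, y, p + hp), _f(model, y, p - hp)
    if fp is None or fm is None:
        raise NoEquilibrium("pump-parameter derivative not evaluable")
    return (fp - fm) / (2.0 * hp)


def find_equilibrium(model, p: float, guess: np.ndarray,
                     tol: float = RESIDUAL_TOL, max_iter: int = 60,
                     fixed_index: int | None = None,
                     solve_p: bool = False) -> tuple[np.ndarray, float]:
    """Newton solve of the autonomous RHS = 0 at pump fraction ``p``.

    With ``fixed_index``/``solve_p`` the state component ``fixed_index`` is
    held and ``p`` becomes the unknown instead (local parametrization used
    around folds).  Returns (state, p).  Raises :class:`NoEquilibrium` on
    non-convergence.
    """
    s = _scales(model)
    rs = _row_scales(model, s)
    y = np.asarray(guess, float).copy()
    pos = None
    if solve_p:
        if fixed_index not in FREE:
            raise ValueError("fixed_index must be a free state index")
        pos = int(np.flatnonzero(FREE == fixed_index)[0])

    def residual(yy, pp):
        r_full = _f(model, yy, pp)
        return None if r_full is None else r_full[FREE]

    r = residual(y, p)
    if r is None:
        raise NoEquilibrium("initial guess outside the admissible region")

    def scaled_norm(rr):
        return float(np.linalg.norm(rr / rs))

    s_free = s[FREE]
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            return y, p
        jy = _jac(model, y, p, s)
        sc = s_free.copy()
        if solve_p:
            a = jy.copy()
            a[:, pos] = _dfdp(model, y, p)[FREE]
            sc[pos] = max(abs(p), 0.1)
        else:
            a = jy
        # row/column equilibration: solve (D_r^-1 A D_c) u = -D_r^-1 r
        a_eq = a / rs[:, None] * sc[None, :]
        try:
            u = np.linalg.solve(a_eq, -r / rs)
        except np.linalg.LinAlgError:
            u, *_ = np.linalg.lstsq(a_eq, -r / rs, rcond=None)
        step = u * sc
        if solve_p:
            dy = step.copy(); dp = step[pos]; dy[pos] = 0.0
        else:
            dy, dp = step, 0.0
        lim = np.max(np.abs(dy) / np.maximum(s_free, 1e-12))
        damp = min(1.0, 2.0 / lim) if lim > 2.0 else 1.0
        n0 = scaled_norm(r)
        for _bt in range(16):
            y_new = y.copy()
            y_new[FREE] += damp * dy
            p_new = p + damp * dp
            r_new = residual(y_new, p_new)
            if r_new is not None and (scaled_norm(r_new) < (1.0 - 1e-4 * damp) * n0
                                      or np.max(np.abs(r_new)) < tol):
                break
            damp *= 0.5
        else:
            raise NoEquilibrium("Newton line search failed")
        y, p, r = y_new, p_new, r_new
    if np.max(np.abs(r)) < tol:
        return y, p
    raise NoEquilibrium(f"no convergence (residual {np.max(np.abs(r)):.2e})")


def _stability(model, y, p, s) -> tuple[np.ndarray, bool]:
    """Jacobian eigenvalues and a stability flag (quasi-neutral modes with
    |Re| < STABILITY_EPS are not allowed to decide the flag)."""
    eig = np.linalg.eigvals(_jac(model, y, p, s))
    return eig, bool(np.max(eig.real) < STABILITY_EPS)


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------

def continue_branch(model, start_state: np.ndarray, p_start: float,
                    p_range: tuple[float, float], dp0: float = 0.01,
                    dp_min: float = 1e-6, dp_max: float = 0.05,
                    max_points: int = 600, direction: int = -1,
                    label: str = "", follow_fold: bool = True,
                    fold_extension: int = 25) -> EquilibriumBranch:
    """Adaptive continuation of an equilibrium branch in the pump fraction.

    Natural (parameter-stepping) continuation with secant predictors while
    the branch is a graph over ``p``; when the parameter step underflows
    (the signature of a fold) the continuation re-parametrizes locally by
    the fastest-varying state coordinate and follows the branch around the
    turning point, so the recorded points span the fold.  Eigenvalues of the
    state Jacobian are recorded at every accepted point.
    """
    s = _scales(model)
    y, p = find_equilibrium(model, p_start, start_state)
    eig, stab = _stability(model, y, p, s)
    branch = EquilibriumBranch(points=[BranchPoint(p, y.copy(), eig, stab)],
                               label=label)
    lo, hi = min(p_range), max(p_range)

    dp = direction * dp0
    y_prev, p_prev = None, None
    while len(branch) < max_points and lo <= p <= hi:
        ok = False
        while abs(dp) >= dp_min:
            p_new = p + dp
            if y_prev is not None and abs(p - p_prev) > 0:
                y_guess = y + (y - y_prev) * (dp / (p - p_prev))
            else:
                y_guess = y.copy()
            try:
                y_new, _ = find_equilibrium(model, p_new, y_guess)
                ok = True
                break
            except NoEquilibrium:
                dp *= 0.5
        if not ok and y_prev is not None:
            # the step underflowed: either a fold, or an isolated singular
            # region (e.g. the vesicle-pool pole or a pitchfork) the solver
            # cannot sit on — try to step across it before giving up
            for mult in (2.0, 4.0, 8.0, 12.0, 16.0, 24.0):
                dp_jump = direction * dp0 * mult
                if not lo <= p + dp_jump <= hi:
                    continue
                y_reset = y.copy()
                y_reset[13:19] = model.y0[13:19]  # re-seed pools past a pole
                for y_guess in (y + (y - y_prev) * (dp_jump / (p - p_prev)),
                                y.copy(), y_reset):
                    try:
                        y_new, _ = find_equilibrium(model, p + dp_jump, y_guess)
                        p_new = p + dp_jump
                        dp = direction * dp0
                        ok = True
                        break
                    except NoEquilibrium:
                        continue
                if ok:
                    break
        if not ok:
            break
        y_prev, p_prev = y, p
        y, p = y_new, p_new
        eig, stab = _stability(model, y, p, s)
        branch.points.append(BranchPoint(p, y.copy(), eig, stab))
        dp = np.clip(dp * 1.4, -dp_max, dp_max) if dp > 0 else \
            np.clip(dp * 1.4, -dp_max, dp_max)

    if not follow_fold or len(branch) < 3 or not (lo < p < hi):
        return branch

    # parameter step underflowed inside the window: follow the branch around
    # the fold by stepping the fastest-varying state coordinate instead
    a, b = branch.points[-2], branch.points[-1]
    k = int(CORE[np.argmax(np.abs((b.y - a.y) / s)[CORE])])
    dw = b.y[k] - a.y[k]
    if dw == 0:
        return branch
    y, p = b.y.copy(), b.p
    for _ in range(fold_extension):
        step_ok = False
        w_step = dw
        while abs(w_step) >= 1e-6 * abs(dw):
            guess = y.copy()
            guess[k] = y[k] + w_step
            try:
                y_new, p_new = find_equilibrium(model, p, guess,
                                                fixed_index=k, solve_p=True)
                step_ok = True
                break
            except NoEquilibrium:
                w_step *= 0.5
        if not step_ok:
            break
        y, p = y_new, p_new
        eig, stab = _stability(model, y, p, s)
        branch.points.append(BranchPoint(p, y.copy(), eig, stab))
        if not (lo <= p <= hi):
            break
        dw = np.sign(dw) * min(abs(w_step) * 1.4, abs(dw) * 4)
    return branch


# ---------------------------------------------------------------------------
# bifurcation detection
# ---------------------------------------------------------------------------

def detect_limit_point(model, branch: EquilibriumBranch,
                       xtol: float = 1e-7) -> BifurcationPoint | None:
    """Locate a fold (sign change of dp/ds along the branch).

    Refined by local parametrization: near the fold the branch is a smooth
    graph p(w) over the fastest-varying state coordinate w, whose extremum is
    found by scalar minimization; accuracy well below 1e-5 in p.
    """
    ps = branch.p
    if len(ps) < 3:
        return None
    dp = np.diff(ps)
    idx = None
    for i in range(len(dp) - 1):
        if dp[i] * dp[i + 1] < 0:
            idx = i + 1
            break
    if idx is None:
        return None
    a, b, c = branch.points[idx - 1], branch.points[idx], branch.points[idx + 1]
    s = _scales(model)
    # core (non-pool) coordinate varying most along the branch (scaled)
    k = int(CORE[np.argmax(np.abs((c.y - a.y) / s)[CORE])])
    w_lo, w_hi = sorted((a.y[k], c.y[k]))
    sign = 1.0 if (b.p > a.p or b.p > c.p) else -1.0
    cache = {"y": b.y.copy(), "p": b.p}

    def neg_p(w: float) -> float:
        guess = cache["y"].copy()
        guess[k] = w
        y_sol, p_sol = find_equilibrium(model, cache["p"], guess,
                                        fixed_index=k, solve_p=True)
        cache["y"], cache["p"] = y_sol, p_sol
        return -sign * p_sol

    res = minimize_scalar(neg_p, bounds=(w_lo, w_hi), method="bounded",
                          options={"xatol": xtol * max(abs(w_hi - w_lo), 1e-12)})
    guess = cache["y"].copy()
    guess[k] = res.x
    y_f, p_f = find_equilibrium(model, cache["p"], guess, fixed_index=k,
                                solve_p=True)
    return BifurcationPoint(kind="limit_point", p=float(p_f), y=y_f,
                            test_value=0.0)


def _max_complex_re(eig: np.ndarray, im_tol: float = 1e-7) -> float:
    cplx = eig[np.abs(eig.imag) > im_tol]
    if cplx.size == 0:
        return -np.inf
    return float(np.max(cplx.real))


def detect_hopf(model, branch: EquilibriumBranch,
                ptol: float = 1e-6) -> list[BifurcationPoint]:
    """Hopf points: a complex-conjugate eigenpair crossing the imaginary axis.

    Sign changes of the maximal complex real part along the branch are
    refined by bisection in ``p`` (Newton-following the equilibrium between
    the bracketing branch points).
    """
    out: list[BifurcationPoint] = []
    mus = [_max_complex_re(pt.eigvals) for pt in branch.points]
    s = _scales(model)
    for i in range(len(mus) - 1):
        m0, m1 = mus[i], mus[i + 1]
        if not (np.isfinite(m0) and np.isfinite(m1)) or m0 * m1 >= 0:
            continue
        a, b = branch.points[i], branch.points[i + 1]
        pa, pb, ya = a.p, b.p, a.y.copy()
        mua = m0
        for _ in range(80):
            if abs(pb - pa) < ptol:
                break
            pm = 0.5 * (pa + pb)
            try:
                ym, _ = find_equilibrium(model, pm, ya)
            except NoEquilibrium:
                break
            mum = _max_complex_re(np.linalg.eigvals(_jac(model, ym, pm, s)))
            if mua * mum <= 0:
                pb = pm
            else:
                pa, ya, mua = pm, ym, mum
        y_h, _ = find_equilibrium(model, 0.5 * (pa + pb), ya)
        out.append(BifurcationPoint(kind="hopf", p=float(0.5 * (pa + pb)),
                                    y=y_h, test_value=0.0))
    return out


# ---------------------------------------------------------------------------
# bistability classification
# ---------------------------------------------------------------------------

def pathological_state(model, p_after: float = 1.0,
                       alpha_guess: float | None = None) -> np.ndarray:
    """The depolarized (pathological) equilibrium at pump fraction p_after.

    Obtained by simulating a deep, long energy deprivation and polishing the
    final state with Newton at the requested pump fraction.
    """
    from .simulate import EDProtocol, Protocols, integrate

    prot = Protocols(ed=EDProtocol(P_min=1e-6, t_start=2.0, t_end=22.0))
    res = integrate(model, prot, t_end=50.0, coarse_dt_ms=500.0)
    y, _ = find_equilibrium(model, p_after, res.y[:, -1])
    return y


def classify_bistability(model, p: float,
                         pathological_guess: np.ndarray | None = None) -> str:
    """Count distinct stable equilibria reachable from a fixed guess ensemble.

    Returns ``monostable_physiological``, ``bistable`` or
    ``monostable_pathological``.
    """
    s = _scales(model)
    guesses = [model.y0.copy()]
    if pathological_guess is None:
        pathological_guess = pathological_state(model)
    guesses.append(pathological_guess)
    guesses.append(0.5 * (model.y0 + pathological_guess))

    found: list[tuple[np.ndarray, bool]] = []
    for g in guesses:
        try:
            y, _ = find_equilibrium(model, p, g)
        except NoEquilibrium:
            # relax towards an attractor first, then polish
            from .simulate import Protocols, integrate
            try:
                res = integrate(model, Protocols(constant_energy=p),
                                t_end=40.0, y0=g, coarse_dt_ms=2000.0)
                y, _ = find_equilibrium(model, p, res.y[:, -1])
            except Exception:
                continue
        # deduplicate on the ion/gate/volume coordinates: the vesicle-pool
        # scale is quasi-neutral and wanders without constituting a distinct
        # physiological state
        if any(np.max(np.abs((y - yy) / s)[CORE]) < 0.5 for yy, _st in found):
            continue
        _, stab = _stability(model, y, p, s)
        found.append((y, stab))

    stable = [y for y, st in found if st]
    if len(stable) >= 2:
        return "bistable"
    if len(stable) == 1:
        v_n = model.consts.F / model.consts.C_n * (
            stable[0][0] + stable[0][1] - stable[0][2] + 2 * stable[0][3]
            - stable[0][4] - model.totals.N_A_n)
        if abs(v_n - model.baseline.V_n0) < 15.0:
            return "monostable_physiological"
        return "monostable_pathological"
    return "none_found"
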