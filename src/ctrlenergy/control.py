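"""Optimal control of linear brain-network dynamics.

The model is the noise-free linear time-invariant system

    dx/dt = A x(t) + B u(t),

where ``A`` is the stability-normalized structural adjacency, ``B`` selects
the control nodes (identity by default: every region is a control node) and
``u(t)`` is the control input.  The transition from an initial state ``x0``
to a target state ``xT`` over a horizon ``T`` minimizes

    int_0^T (xT - x)' S (xT - x) + rho u'u dt,   s.t. x(0) = x0, x(T) = xT,

with ``S`` a 0-1 diagonal matrix restricting the state penalty to a
constrained node set (the fronto-parietal system by default) and ``rho > 0``
weighting the energy term.  Applying the Pontryagin minimum principle yields
the optimal input ``u* = -(1/2 rho) B' p*`` where the costate ``p*`` solves,
jointly with the state, the affine augmented system

    d/dt [x; p] = Atilde [x; p] + btilde,
    Atilde = [[A, -(1/2 rho) B B'], [-2 S, -A']],   btilde = [0; 2 S xT].

The two-point boundary-value problem is solved by shooting: with
``exp(Atilde T)`` partitioned into N x N blocks ``E11, E12, E21, E22`` and
``c = Atilde^{-1} (exp(Atilde T) - I) btilde`` split into ``c1, c2``,

    p(0) = E12^{-1} (xT - E11 x0 - c1),

after which the trajectory follows by repeated application of the exact
one-step propagator ``exp(Atilde dt)`` with the constant forcing term (no
Euler discretization error).  The per-node control energy is
``E_i = int_0^T u_i*(t)^2 dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm, lu_factor, lu_solve, solve

from .errors import (
    IllConditionedError,
    ParameterError,
    SolverError,
    ValidationError,
)
from .network import Connectome, NormalizedMatrix, normalize_adjacency

CONDITION_LIMIT = 1e12


@dataclass
class BrainState:
    """A vector of per-region activity magnitudes at one time point."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("brain state contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


def build_state(
    systems: np.ndarray,
    kind: str,
    *,
    system: str | None = None,
    magnitude: float = 1.0,
    noise_sd: float | None = None,
    count: int | None = None,
    seed: int | None = None,
    path: str | Path | None = None,
    n_nodes: int | None = None,
):
    """Construct initial/target brain states.

    kind:
        ``baseline``            zero vector;
        ``system_indicator``    ``magnitude`` on the nodes of ``system``, 0 elsewhere;
        ``noisy``               ``count`` seeded copies of the indicator with Gaussian
                                perturbation (sd ``noise_sd``) on the system nodes only;
        ``continuous_from_file`` arbitrary finite vector loaded from a text file
                                (supports activation-map targets).
    """
    systems = np.asarray(systems)
    n = len(systems) if n_nodes is None else n_nodes
    if kind == "baseline":
        return BrainState(np.zeros(n))
    if kind == "continuous_from_file":
        vec = np.loadtxt(path).ravel()
        if len(vec) != n:
            raise ValidationError(
                f"state vector length {len(vec)} does not match n_nodes {n}"
            )
        return BrainState(vec)
    if system is None:
        raise ParameterError(f"kind={kind!r} requires a system label")
    mask = systems == system
    if not mask.any():
        raise ValidationError(f"unknown system label {system!r}")
    base = np.where(mask, float(magnitude), 0.0)
    if kind == "system_indicator":
        return BrainState(base)
    if kind == "noisy":
        if noise_sd is None or count is None:
            raise ParameterError("kind='noisy' requires noise_sd and count")
        rng = np.random.default_rng(seed)
        out = np.tile(base, (count, 1))
        out[:, mask] += noise_sd * rng.standard_normal((count, int(mask.sum())))
        return [BrainState(v) for v in out]
    raise ParameterError(f"unknown state kind {kind!r}")


@dataclass
class ControlTask:
    """A single state-transition optimal control problem."""

    normalized_A: NormalizedMatrix
    x0: BrainState
    xT: BrainState
    control_set: np.ndarray | None = None  # None -> all nodes (B = identity)
    constrained_set: np.ndarray | None = None  # None -> all nodes
    horizon_T: float = 1.0
    rho: float = 1.0
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.normalized_A.mode != "control":
            raise ValidationError("ControlTask requires a mode='control' matrix")
        n = self.normalized_A.matrix.shape[0]
        if len(self.x0) != n or len(self.xT) != n:
            raise ValidationError("state length does not match the network size")
        if self.rho <= 0:
            raise ParameterError("rho must be positive")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        steps = self.horizon_T / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ParameterError("horizon_T must be an integer multiple of dt")
        if self.control_set is not None:
            self.control_set = np.asarray(self.control_set, dtype=int)
            if self.control_set.size == 0:
                raise ParameterError("control_set must be nonempty")
        if self.constrained_set is None:
            self.constrained_set = np.arange(n)
        else:
            self.constrained_set = np.asarray(self.constrained_set, dtype=int)
            if self.constrained_set.size == 0:
                raise ParameterError("constrained_set must be nonempty")

    @property
    def n_nodes(self) -> int:
        return self.normalized_A.matrix.shape[0]

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_T / self.dt))

    def b_diag(self) -> np.ndarray:
        b = np.zeros(self.n_nodes)
        if self.control_set is None:
            b[:] = 1.0
        else:
            b[self.control_set] = 1.0
        return b

    def s_diag(self) -> np.ndarray:
        s = np.zeros(self.n_nodes)
        s[self.constrained_set] = 1.0
        return s


@dataclass
class AugmentedSystem:
    a_tilde: np.ndarray
    b_tilde: np.ndarray
    e11: np.ndarray
    e12: np.ndarray
    e21: np.ndarray
    e22: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    e12_condition: float


@dataclass
class ControlSolution:
    times: np.ndarray
    states: np.ndarray  # (steps+1, N)
    costates: np.ndarray
    inputs: np.ndarray
    nodal_energy: np.ndarray
    total_energy: float
    distance_series: np.ndarray
    terminal_error: float


def build_augmented_system(task: ControlTask) -> AugmentedSystem:
    """Assemble ``Atilde``/``btilde`` and the shooting blocks of ``exp(Atilde T)``.

    ``c`` is obtained by a linear solve against ``Atilde`` (never an explicit
    inverse); the residual is checked against ``1e-8 * ||btilde||``.
    """
    n = task.n_nodes
    a = task.normalized_A.matrix
    b = task.b_diag()
    s = task.s_diag()
    bbt = np.diag(b)  # B B' for a 0-1 diagonal B
    a_tilde = np.block(
        [[a, -bbt / (2.0 * task.rho)], [-2.0 * np.diag(s), -a.T]]
    )
    b_tilde = np.concatenate([np.zeros(n), 2.0 * s * task.xT.values])
    e_t = expm(a_tilde * task.horizon_T)
    rhs = (e_t - np.eye(2 * n)) @ b_tilde
    try:
        c = solve(a_tilde, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError("augmented system matrix is numerically singular") from exc
    b_norm = np.linalg.norm(b_tilde)
    resid = np.linalg.norm(a_tilde @ c - rhs)
    if b_norm > 0 and resid > 1e-8 * b_norm:
        raise SolverError(
            f"augmented-system solve residual {resid:.3e} exceeds 1e-8*||btilde||"
        )
    e11, e12 = e_t[:n, :n], e_t[:n, n:]
    e21, e22 = e_t[n:, :n], e_t[n:, n:]
    cond = float(np.linalg.cond(e12))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise IllConditionedError(
            f"E12 condition number {cond:.3e} exceeds {CONDITION_LIMIT:.0e}; "
            "consider a larger rho or a shorter horizon"
        )
    return AugmentedSystem(
        a_tilde=a_tilde,
        b_tilde=b_tilde,
        e11=e11,
        e12=e12,
        e21=e21,
        e22=e22,
        c1=c[:n],
        c2=c[n:],
        e12_condition=cond,
    )


def solve_optimal_control(task: ControlTask) -> ControlSolution:
    """Solve the two-point boundary-value problem and integrate the trajectory.

    Uses the exact one-step propagator ``exp(Atilde dt)`` of the affine
    augmented system, so the only discretization is the storage grid.
    """
    aug = build_augmented_system(task)
    n = task.n_nodes
    x0, xt = task.x0.values, task.xT.values
    p0 = solve(aug.e12, xt - aug.e11 @ x0 - aug.c1)

    steps = task.n_steps
    phi = expm(aug.a_tilde * task.dt)
    rhs = (phi - np.eye(2 * n)) @ aug.b_tilde
    lu = lu_factor(aug.a_tilde)
    delta = lu_solve(lu, rhs)

    z = np.empty((steps + 1, 2 * n))
    z[0] = np.concatenate([x0, p0])
    for k in range(steps):
        z[k + 1] = phi @ z[k] + delta
    if not np.all(np.isfinite(z)):
        raise SolverError("non-finite values encountered during propagation")

    states = z[:, :n]
    costates = z[:, n:]
    inputs = -(1.0 / (2.0 * task.rho)) * (task.b_diag()[None, :] * costates)
    times = np.arange(steps + 1) * task.dt
    nodal_energy = np.trapezoid(inputs**2, dx=task.dt, axis=0)
    diff = xt[None, :] - states
    distance_series = np.linalg.norm(diff[:, task.constrained_set], axis=1)
    terminal_error = float(np.max(np.abs(states[-1] - xt)))
    return ControlSolution(
        times=times,
        states=states,
        costates=costates,
        inputs=inputs,
        nodal_energy=nodal_energy,
        total_energy=float(nodal_energy.sum()),
        distance_series=distance_series,
        terminal_error=terminal_error,
    )


def summarize_trajectory(
    solution: ControlSolution, systems: np.ndarray
) -> dict:
    """Energy and distance summaries of a solved trajectory.

    System-level energy is the mean nodal energy over the system's nodes;
    whole-brain energy is the mean over all nodes; total trajectory distance
    is the sum of the per-step distance series.
    """
    systems = np.asarray(systems)
    summary = {
        "whole_brain_energy": float(solution.nodal_energy.mean()),
        "total_energy": solution.total_energy,
        "total_distance": float(solution.distance_series.sum()),
        "terminal_error": solution.terminal_error,
        "system_energy": {
            str(lab): float(solution.nodal_energy[systems == lab].mean())
            for lab in np.unique(systems)
        },
    }
    return summary


@dataclass
class CohortEnergyResult:
    nodal: pd.DataFrame  # subject_id x node columns
    summaries: pd.DataFrame  # per-subject whole-brain/system energy + diagnostics


def cohort_energy(
    connectomes,
    subject_ids,
    systems: np.ndarray,
    *,
    target_system: str = "frontoparietal",
    target_state: BrainState | None = None,
    initial_state: BrainState | None = None,
    constrain: str = "fp",
    rho: float = 1.0,
    horizon_T: float = 1.0,
    dt: float = 0.001,
    literal_control: bool = False,
) -> CohortEnergyResult:
    """Per-subject control energies for the baseline -> target transition.

    ``constrain='fp'`` restricts the state penalty (matrix ``S``) to the
    target system's nodes; ``constrain='all'`` penalizes every node.
    """
    systems = np.asarray(systems)
    if constrain not in ("fp", "all"):
        raise ParameterError("constrain must be 'fp' or 'all'")
    rows = []
    summaries = []
    for sid, conn in zip(subject_ids, connectomes):
        norm = normalize_adjacency(conn, "control", literal_control=literal_control)
        x0 = initial_state or build_state(systems, "baseline")
        xt = target_state or build_state(
            systems, "system_indicator", system=target_system
        )
        constrained = (
            np.flatnonzero(systems == target_system) if constrain == "fp" else None
        )
        task = ControlTask(
            normalized_A=norm,
            x0=x0,
            xT=xt,
            constrained_set=constrained,
            horizon_T=horizon_T,
            rho=rho,
            dt=dt,
        )
        sol = solve_optimal_control(task)
        rows.append(sol.nodal_energy)
        summ = summarize_trajectory(sol, systems)
        flat = {
            "subject_id": sid,
            "whole_brain_energy": summ["whole_brain_energy"],
            "total_energy": summ["total_energy"],
            "total_distance": summ["total_distance"],
            "terminal_error": summ["terminal_error"],
        }
        flat.update(
            {f"energy_{lab}": v for lab, v in summ["system_energy"].items()}
        )
        summaries.append(flat)
    node_cols = (
        connectomes[0].node_labels
        if len(connectomes)
        else [f"n{i:03d}" for i in range(len(systems))]
    )
    nodal = pd.DataFrame(np.asarray(rows), columns=node_cols)
    nodal.insert(0, "subject_id", list(subject_ids))
    return CohortEnergyResult(nodal=nodal, summaries=pd.DataFrame(summaries))
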