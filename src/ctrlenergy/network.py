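"""Connectome container, adjacency normalization, and graph metrics.

A connectome is an undirected, nonnegative, weighted adjacency matrix with a
fixed a-priori partition of nodes into cognitive systems.  Three normalization
variants of the raw matrix ``A`` (spectral radius ``xi0``) are used downstream:

``control``
    ``A / (1 + xi0) - I`` — a stable matrix (all eigenvalues negative) used as
    the drift term of the linear dynamical model.
``modal``
    ``A / (1 + xi0)`` — spectral radius below one, used for modal
    controllability.
``modularity``
    ``A / xi0`` — nonnegative with unit spectral radius, used when computing
    the modularity quality ``Q`` (subtracting the identity would make ``Q``
    uninterpretable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

MODES = ("control", "modal", "modularity")


@dataclass
class Connectome:
    """Symmetric nonnegative weighted adjacency with node metadata.

    Parameters
    ----------
    weights
        ``(N, N)`` symmetric nonnegative matrix with a zero diagonal.
    node_labels
        Length-``N`` sequence of node names.
    systems
        Length-``N`` sequence mapping each node to its system label.
    """

    weights: np.ndarray
    node_labels: np.ndarray
    systems: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_labels = np.asarray(self.node_labels)
        self.systems = np.asarray(self.systems)
        self.validate()

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {w.shape}")
        n = w.shape[0]
        if len(self.node_labels) != n or len(self.systems) != n:
            raise ValidationError("node_labels/systems length must match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValidationError("adjacency contains non-finite entries")
        if np.any(w < 0):
            raise ValidationError("adjacency contains negative weights")
        if np.any(np.diag(w) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.array_equal(w, w.T):
            raise ValidationError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def system_indices(self, system: str) -> np.ndarray:
        idx = np.flatnonzero(self.systems == system)
        if idx.size == 0:
            raise ValidationError(f"unknown system label {system!r}")
        return idx

    def spectral_radius(self) -> float:
        # symmetric nonnegative matrix: Perron root = largest eigenvalue
        return float(np.linalg.eigvalsh(self.weights)[-1])


@dataclass
class NormalizedMatrix:
    matrix: np.ndarray
    mode: str
    spectral_radius: float


@dataclass
class GraphMetricsResult:
    modal_controllability: np.ndarray
    modularity_q: float
    participation: np.ndarray
    within_fp_strength: float
    fp_between_strength: float
    total_strength: float
    fp_participation_mean: float = field(default=np.nan)


def normalize_adjacency(
    connectome: Connectome, mode: str, *, literal_control: bool = False
) -> NormalizedMatrix:
    """Scale the raw adjacency by its largest eigenvalue.

    ``mode='control'`` additionally subtracts the identity so that the result
    is strictly stable.  With ``literal_control=True`` the control variant is
    ``A/xi0 - I`` (marginally stable: one zero eigenvalue); the default uses
    ``A/(1+xi0) - I``.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    xi0 = connectome.spectral_radius()
    if xi0 <= 0:
        raise DegenerateInputError("all-zero adjacency: spectral radius is 0")
    a = connectome.weights
    if mode == "control":
        denom = xi0 if literal_control else 1.0 + xi0
        m = a / denom - np.eye(connectome.n_nodes)
    elif mode == "modal":
        m = a / (1.0 + xi0)
    else:  # modularity
        m = a / xi0
    return NormalizedMatrix(matrix=m, mode=mode, spectral_radius=xi0)


def modal_controllability(normalized: NormalizedMatrix) -> np.ndarray:
    """Per-node modal controllability ``phi_i = sum_j (1 - lambda_j^2) v_ij^2``.

    Summarizes a node's capacity to push the system into hard-to-reach
    dynamic modes; computed from the eigenmodes of the ``modal``-scaled
    adjacency.
    """
    if normalized.mode != "modal":
        raise ValidationError("modal_controllability requires mode='modal'")
    m = normalized.matrix
    if not np.allclose(m, m.T, atol=0.0, rtol=0.0):
        raise ValidationError("modal controllability requires a symmetric matrix")
    lam, vec = np.linalg.eigh(m)
    return (vec**2) @ (1.0 - lam**2)


def participation_coefficient(weights: np.ndarray, systems: np.ndarray) -> np.ndarray:
    """Participation coefficient ``P_i = 1 - sum_s (k_is / k_i)^2``.

    Isolated nodes (zero strength) get ``P_i = 0``.
    """
    strength = weights.sum(axis=1)
    labels = np.unique(systems)
    frac_sq = np.zeros_like(strength)
    with np.errstate(divide="ignore", invalid="ignore"):
        for lab in labels:
            k_is = weights[:, systems == lab].sum(axis=1)
            frac_sq += np.where(strength > 0, (k_is / np.where(strength > 0, strength, 1.0)) ** 2, 0.0)
    part = 1.0 - frac_sq
    isolated = strength == 0
    if isolated.any():
        logger.info("participation: %d isolated node(s) set to 0", int(isolated.sum()))
        part[isolated] = 0.0
    return part


def modularity_q(weights: np.ndarray, systems: np.ndarray) -> float:
    """Newman weighted modularity of a fixed partition (no community detection)."""
    two_m = weights.sum()
    if two_m <= 0:
        raise DegenerateInputError("modularity undefined for an all-zero matrix")
    k = weights.sum(axis=1)
    same = systems[:, None] == systems[None, :]
    q = ((weights - np.outer(k, k) / two_m)[same]).sum() / two_m
    return float(q)


def graph_metrics(
    connectome: Connectome, fp_system: str = "frontoparietal"
) -> GraphMetricsResult:
    """Graph metrics used as sensitivity covariates in the developmental models.

    ``Q`` is computed on the matrix scaled by its largest eigenvalue (no
    identity subtraction); participation and strengths use the raw weights.
    """
    w = connectome.weights
    systems = connectome.systems
    norm_mod = normalize_adjacency(connectome, "modularity")
    q = modularity_q(norm_mod.matrix, systems)
    part = participation_coefficient(w, systems)
    phi = modal_controllability(normalize_adjacency(connectome, "modal"))
    fp = connectome.system_indices(fp_system)
    in_fp = np.zeros(connectome.n_nodes, dtype=bool)
    in_fp[fp] = True
    triu = np.triu_indices_from(w, k=1)
    edge_w = w[triu]
    both_fp = in_fp[triu[0]] & in_fp[triu[1]]
    one_fp = in_fp[triu[0]] ^ in_fp[triu[1]]
    return GraphMetricsResult(
        modal_controllability=phi,
        modularity_q=q,
        participation=part,
        within_fp_strength=float(edge_w[both_fp].sum()),
        fp_between_strength=float(edge_w[one_fp].sum()),
        total_strength=float(edge_w.sum()),
        fp_participation_mean=float(part[fp].mean()),
    )
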