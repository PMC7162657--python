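"""Seeded synthetic connectome cohorts with planted developmental effects.

The generator emulates, at desk scale, the statistical structure of a
probabilistic-tractography connectome cohort of youths:

* symmetric, nonnegative, zero-diagonal probability-weighted matrices with a
  modular (system-block) structure — within-system mean weight exceeds
  between-system mean weight;
* an age-linked strengthening of fronto-parietal (FP) connectivity: within-FP
  edge weights are multiplied by ``1 + gamma * (age - lo) / (hi - lo)``;
* a planted mediation chain running through connectivity: a standardized
  latent ``L = a * z(age) + noise`` multiplies edges incident to two
  designated "cingulate" nodes inside the FP block by ``1 + c * L``, and the
  executive-function score is ``b * L + f * z(age) + noise`` — so any
  association between cingulate control energy and executive function must be
  carried by the connectomes themselves;
* covariates with realistic structure (in-scanner motion declining with age).

Edge weights follow a lognormal multiplicative law around block means, a
heavy-tailed choice mimicking tractography connection probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError, ValidationError
from .network import Connectome

logger = logging.getLogger(__name__)

DEFAULT_SYSTEMS = (
    "visual",
    "motor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
    "subcortical",
)

FP_SYSTEM = "frontoparietal"

PHENOTYPE_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "handedness",
    "motion",
    "tbv",
    "network_strength",
    "ef_score",
)


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are desk-scale study conditions: 300 subjects, 64 nodes in 8
    equal systems (one of them fronto-parietal, containing the two designated
    cingulate nodes), ages 8-23 years.
    """

    n_subjects: int = 300
    n_nodes: int = 64
    partition_sizes: tuple[int, ...] | None = None
    system_names: tuple[str, ...] = DEFAULT_SYSTEMS
    age_range: tuple[float, float] = (8.0, 23.0)
    within_weight_mean: float = 0.2
    between_weight_mean: float = 0.05
    weight_noise_sd: float = 0.5
    age_effect_gamma: float = 0.3
    latent_loading_a: float = 0.6
    ef_loading_b: float = 0.5
    ef_age_loading_f: float = 0.3
    cingulate_loading_c: float = 0.3
    motion_age_r: float = -0.3
    n_cingulate: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition_sizes is None:
            k = len(self.system_names)
            if self.n_nodes % k != 0:
                raise ParameterError(
                    f"n_nodes={self.n_nodes} not divisible into {k} equal systems; "
                    "pass partition_sizes explicitly"
                )
            self.partition_sizes = (self.n_nodes // k,) * k
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if sum(self.partition_sizes) != self.n_nodes:
            raise ParameterError(
                f"partition sizes {self.partition_sizes} do not sum to n_nodes={self.n_nodes}"
            )
        if len(self.partition_sizes) != len(self.system_names):
            raise ParameterError("partition_sizes and system_names lengths differ")
        if FP_SYSTEM not in self.system_names:
            raise ParameterError(f"system_names must include {FP_SYSTEM!r}")
        if self.within_weight_mean <= 0 or self.between_weight_mean <= 0:
            raise ParameterError("weight means must be > 0")
        if self.between_weight_mean >= self.within_weight_mean:
            raise ParameterError("between_weight_mean must be < within_weight_mean")
        if not self.age_range[0] < self.age_range[1]:
            raise ParameterError("age_range lower bound must be below upper bound")
        if self.weight_noise_sd < 0:
            raise ParameterError("weight_noise_sd must be >= 0")
        fp_size = dict(zip(self.system_names, self.partition_sizes))[FP_SYSTEM]
        if self.n_cingulate > fp_size:
            raise ParameterError("n_cingulate exceeds the fronto-parietal block size")
        if not abs(self.latent_loading_a) <= 1:
            raise ParameterError("latent_loading_a must lie in [-1, 1]")
        resid = 1.0 - self.ef_var_explained()
        if resid < 0:
            raise ParameterError("ef loadings imply variance > 1; reduce b and/or f")

    def ef_var_explained(self) -> float:
        a, b, f = self.latent_loading_a, self.ef_loading_b, self.ef_age_loading_f
        # var(b*L + f*z) with corr(L, z) = a
        return b * b + f * f + 2 * a * b * f

    def systems_per_node(self) -> np.ndarray:
        return np.repeat(np.asarray(self.system_names), np.asarray(self.partition_sizes))

    def fp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.systems_per_node() == FP_SYSTEM)

    def cingulate_indices(self) -> np.ndarray:
        return self.fp_indices()[: self.n_cingulate]


@dataclass
class Cohort:
    connectomes: list[Connectome]
    phenotypes: pd.DataFrame
    systems: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.systems is None and self.connectomes:
            self.systems = self.connectomes[0].systems
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.phenotypes.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        if self.phenotypes.isna().any().any():
            bad = self.phenotypes.columns[self.phenotypes.isna().any()].tolist()
            raise ValidationError(f"phenotype table has missing values in: {bad}")
        if len(self.phenotypes) != len(self.connectomes):
            raise ValidationError("one phenotype row per connectome is required")

    @property
    def n_subjects(self) -> int:
        return len(self.connectomes)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate a fully reproducible cohort of connectomes and phenotypes."""
    rng = np.random.default_rng(spec.seed)
    n, nn = spec.n_subjects, spec.n_nodes
    lo, hi = spec.age_range

    age = rng.uniform(lo, hi, size=n)
    z_age = _standardize(age)
    sex = rng.integers(0, 2, size=n).astype(float)
    handedness = (rng.random(n) < 0.85).astype(float)

    # motion declines with age (default r ~ -0.3), stressing covariate adjustment
    r_m = spec.motion_age_r
    motion_z = r_m * z_age + np.sqrt(max(0.0, 1 - r_m**2)) * rng.standard_normal(n)
    motion = np.clip(0.08 + 0.03 * motion_z, 0.005, None)

    tbv = 1250.0 + 60.0 * sex + 90.0 * rng.standard_normal(n)

    a = spec.latent_loading_a
    latent = a * z_age + np.sqrt(1 - a**2) * rng.standard_normal(n)
    # winsorize at +/-3 sd: keeps the multiplicative edge factor 1 + c*L
    # positive for |c| < 1/3 without materially changing the planted paths
    latent = np.clip(latent, -3.0, 3.0)

    b, f = spec.ef_loading_b, spec.ef_age_loading_f
    resid_sd = np.sqrt(max(0.0, 1.0 - spec.ef_var_explained()))
    ef = b * latent + f * z_age + resid_sd * rng.standard_normal(n)

    systems = spec.systems_per_node()
    labels = np.array([f"n{i:03d}" for i in range(nn)])
    same_system = systems[:, None] == systems[None, :]
    block_mean = np.where(same_system, spec.within_weight_mean, spec.between_weight_mean)
    iu, ju = np.triu_indices(nn, k=1)

    fp = spec.fp_indices()
    in_fp = np.zeros(nn, dtype=bool)
    in_fp[fp] = True
    within_fp_edge = in_fp[iu] & in_fp[ju]
    cing = spec.cingulate_indices()
    is_cing = np.zeros(nn, dtype=bool)
    is_cing[cing] = True
    cing_edge = is_cing[iu] | is_cing[ju]

    sigma = spec.weight_noise_sd
    # lognormal noise with unit mean so block means are expectations
    mu = -0.5 * sigma**2

    age_factor = 1.0 + spec.age_effect_gamma * (age - lo) / (hi - lo)
    cing_factor = 1.0 + spec.cingulate_loading_c * latent

    connectomes: list[Connectome] = []
    strengths = np.empty(n)
    for s in range(n):
        if age_factor[s] <= 0:
            raise GenerationError(
                f"subject {s}: age_effect_gamma yields nonpositive scale {age_factor[s]:.4g}"
            )
        if cing_factor[s] <= 0:
            raise GenerationError(
                f"subject {s}: cingulate_loading_c yields nonpositive scale "
                f"{cing_factor[s]:.4g} (latent={latent[s]:.3g})"
            )
        noise = np.exp(mu + sigma * rng.standard_normal(iu.size))
        edge = block_mean[iu, ju] * noise
        edge[within_fp_edge] *= age_factor[s]
        edge[cing_edge] *= cing_factor[s]
        w = np.zeros((nn, nn))
        w[iu, ju] = edge
        w[ju, iu] = edge
        strengths[s] = edge.sum()
        connectomes.append(Connectome(weights=w, node_labels=labels, systems=systems))

    phenotypes = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "handedness": handedness,
            "motion": motion,
            "tbv": tbv,
            "network_strength": strengths,
            "ef_score": ef,
        }
    )
    return Cohort(connectomes=connectomes, phenotypes=phenotypes, systems=systems)


# ---------------------------------------------------------------------------
# text serialization (tab-separated, one full matrix per subject)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort to ``directory``; returns the manifest path.

    Layout: ``manifest.tsv`` (subject_id, path), ``phenotypes.tsv``,
    ``partition.tsv`` (node_index, node_name, system_label) and one
    full-precision tab-separated matrix file per subject.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat_dir = directory / "matrices"
    mat_dir.mkdir(exist_ok=True)
    rows = []
    for sid, conn in zip(cohort.phenotypes["subject_id"], cohort.connectomes):
        rel = f"matrices/{sid}.tsv"
        np.savetxt(directory / rel, conn.weights, fmt="%.17e", delimiter="\t")
        rows.append((sid, rel))
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows, columns=["subject_id", "path"]).to_csv(
        manifest, sep="\t", index=False
    )
    cohort.phenotypes.to_csv(directory / "phenotypes.tsv", sep="\t", index=False)
    conn0 = cohort.connectomes[0]
    pd.DataFrame(
        {
            "node_index": np.arange(conn0.n_nodes),
            "node_name": conn0.node_labels,
            "system_label": conn0.systems,
        }
    ).to_csv(directory / "partition.tsv", sep="\t", index=False)
    return manifest


def read_partition(path: str | Path) -> pd.DataFrame:
    part = pd.read_csv(path, sep="\t")
    required = {"node_index", "node_name", "system_label"}
    if not required.issubset(part.columns):
        raise ValidationError(f"partition table must have columns {sorted(required)}")
    return part.sort_values("node_index").reset_index(drop=True)


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    phenotypes = pd.read_csv(directory / "phenotypes.tsv", sep="\t")
    if phenotypes.isna().any().any():
        bad = phenotypes.columns[phenotypes.isna().any()].tolist()
        raise ValidationError(f"phenotype table has missing values in: {bad}")
    part = read_partition(directory / "partition.tsv")
    labels = part["node_name"].to_numpy()
    systems = part["system_label"].to_numpy()
    connectomes = []
    for sid, rel in zip(manifest["subject_id"], manifest["path"]):
        path = directory / rel
        if not path.exists():
            raise IOError(f"matrix file missing for subject {sid}: {path}")
        w = np.loadtxt(path, delimiter="\t")
        if not np.array_equal(w, w.T):
            raise ValidationError(f"matrix for subject {sid} is not symmetric")
        connectomes.append(Connectome(weights=w, node_labels=labels, systems=systems))
    order = {s: i for i, s in enumerate(manifest["subject_id"])}
    phenotypes = phenotypes.sort_values(
        "subject_id", key=lambda s: s.map(order)
    ).reset_index(drop=True)
    if list(phenotypes["subject_id"]) != list(manifest["subject_id"]):
        raise ValidationError("phenotype table does not match the manifest subjects")
    return Cohort(connectomes=connectomes, phenotypes=phenotypes, systems=systems)
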