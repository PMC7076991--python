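"""Synthetic methylation-array generators with planted ground truth.

Each generator emulates one of the statistical structures the modelling
stack is meant to recover from real arrays:

* discrete latent classes with class-specific differentially methylated
  CpGs (tumour-subtype-like structure),
* a continuous age covariate with monotone per-CpG drift in logit space
  (epigenetic-clock-like signal),
* Dirichlet cell-type mixtures over lineage-structured reference
  methylomes (bulk deconvolution),
* a binary exposure with a geometrically decaying effect-size spectrum
  (EWAS-like signal).

The noise model is logit-normal throughout: per-CpG baselines are drawn
in logit space from a bimodal mixture (most loci near beta 0.1 or 0.9),
effects and Gaussian noise are added on the logit scale, and the sigmoid
maps back to (0, 1) — so generated betas are bounded and strictly inside
the unit interval without clipping.  Every generator is bit-reproducible
under a fixed seed and returns a :class:`SyntheticTruth` holding the
planted labels, covariates, proportions and signed effect sizes needed
for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import MethylationArray
from .errors import ConfigError


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated array."""

    seed: int
    class_labels: pd.Series | None = None
    age: pd.Series | None = None
    proportions: pd.DataFrame | None = None
    lineage: list[int] | None = None  # parent index per node, -1 for root
    effect_cpgs: dict[str, dict[str, float]] = field(default_factory=dict)
    references: pd.DataFrame | None = None  # cell types x CpGs, beta scale

    def to_json(self, path):
        """Serialise as a sidecar JSON (effect maps, proportions, lineage)."""
        payload: dict = {"seed": self.seed, "effect_cpgs": self.effect_cpgs}
        if self.class_labels is not None:
            payload["class_labels"] = self.class_labels.astype(str).to_dict()
        if self.age is not None:
            payload["age"] = self.age.astype(float).to_dict()
        if self.proportions is not None:
            payload["proportions"] = {
                s: row.tolist() for s, row in self.proportions.iterrows()
            }
            payload["cell_types"] = list(self.proportions.columns)
        if self.lineage is not None:
            payload["lineage"] = list(self.lineage)
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)
        return path


def _baseline_logits(rng: np.random.Generator, n_cpgs: int) -> np.ndarray:
    """Bimodal baseline: most CpGs near beta ~0.1 or ~0.9, a few intermediate."""
    component = rng.choice(3, size=n_cpgs, p=[0.45, 0.45, 0.10])
    centers = np.array([-2.2, 2.2, 0.0])[component]
    scales = np.array([0.5, 0.5, 0.7])[component]
    return centers + scales * rng.standard_normal(n_cpgs)


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _check_dims(n_samples, n_cpgs, n_informative=None):
    if n_samples <= 0 or n_cpgs <= 0:
        raise ConfigError(f"non-positive dimensions: n_samples={n_samples}, n_cpgs={n_cpgs}")
    if n_informative is not None and not 0 <= n_informative <= n_cpgs:
        raise ConfigError(f"n_informative={n_informative} out of [0, {n_cpgs}]")


def generate_cluster_dataset(
    n_samples: int = 300,
    n_cpgs: int = 500,
    n_classes: int = 3,
    n_informative: int = 60,
    effect: float = 4.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[MethylationArray, SyntheticTruth]:
    """Discrete classes with class-specific hyper-methylated CpG blocks.

    The informative CpGs are divided evenly among the classes; each block is
    shifted by ``effect`` logit units in samples of its class.  Labels are
    balanced up to rounding and stored in pheno column ``"class"``.
    """
    _check_dims(n_samples, n_cpgs, n_informative)
    if n_classes < 2:
        raise ConfigError(f"n_classes must be >= 2, got {n_classes}")
    rng = np.random.default_rng(seed)

    cpg_ids = _ids("cg", n_cpgs)
    sample_ids = _ids("s", n_samples)
    baseline = _baseline_logits(rng, n_cpgs)

    labels = np.repeat(np.arange(n_classes), int(np.ceil(n_samples / n_classes)))[:n_samples]
    labels = labels[rng.permutation(n_samples)]

    informative = rng.choice(n_cpgs, size=n_informative, replace=False)
    owner = np.repeat(np.arange(n_classes), int(np.ceil(n_informative / n_classes)))[:n_informative]

    shift = np.zeros((n_classes, n_cpgs))
    shift[owner, informative] = effect

    logits = baseline[None, :] + shift[labels] + noise_sd * rng.standard_normal((n_samples, n_cpgs))
    beta = _sigmoid(logits)

    arr = MethylationArray(
        pd.DataFrame(beta, index=sample_ids, columns=cpg_ids),
        pd.DataFrame({"class": [f"class{c}" for c in labels]}, index=sample_ids),
        validate=False,
    )
    truth = SyntheticTruth(
        seed=seed,
        class_labels=arr.pheno["class"],
        effect_cpgs={"cluster": {cpg_ids[j]: float(effect) for j in informative}},
    )
    return arr, truth


def generate_age_dataset(
    n_samples: int = 500,
    n_cpgs: int = 500,
    n_informative: int = 50,
    slope_range: tuple[float, float] = (0.02, 0.05),
    age_range: tuple[float, float] = (15.0, 95.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[MethylationArray, SyntheticTruth]:
    """Continuous ages with linear logit-scale drift at informative CpGs.

    Ages are uniform on ``age_range`` (stored in pheno column ``"age"``);
    each informative CpG drifts at a signed per-year slope whose magnitude
    is uniform on ``slope_range``.  Drift is centred at the mid-range age so
    baselines stay in the bimodal regime.
    """
    _check_dims(n_samples, n_cpgs, n_informative)
    if not age_range[1] > age_range[0]:
        raise ConfigError(f"degenerate age_range {age_range}")
    rng = np.random.default_rng(seed)

    cpg_ids = _ids("cg", n_cpgs)
    sample_ids = _ids("s", n_samples)
    baseline = _baseline_logits(rng, n_cpgs)

    ages = rng.uniform(age_range[0], age_range[1], size=n_samples)
    informative = rng.choice(n_cpgs, size=n_informative, replace=False)
    slopes = np.zeros(n_cpgs)
    magnitudes = rng.uniform(slope_range[0], slope_range[1], size=n_informative)
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    slopes[informative] = magnitudes * signs

    mid = 0.5 * (age_range[0] + age_range[1])
    logits = (
        baseline[None, :]
        + np.outer(ages - mid, slopes)
        + noise_sd * rng.standard_normal((n_samples, n_cpgs))
    )
    beta = _sigmoid(logits)

    arr = MethylationArray(
        pd.DataFrame(beta, index=sample_ids, columns=cpg_ids),
        pd.DataFrame({"age": ages}, index=sample_ids),
        validate=False,
    )
    truth = SyntheticTruth(
        seed=seed,
        age=arr.pheno["age"],
        effect_cpgs={"age": {cpg_ids[j]: float(slopes[j]) for j in informative}},
    )
    return arr, truth


def generate_mixture_dataset(
    n_samples: int = 300,
    n_cpgs: int = 500,
    n_celltypes: int = 4,
    dirichlet_alpha: float | list[float] = 1.0,
    lineage_depth: int = 2,
    divergence: float = 2.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    level_decay: float = 0.3,
) -> tuple[MethylationArray, SyntheticTruth]:
    """Dirichlet cell-type mixtures over lineage-structured references.

    Reference methylomes are generated by recursive perturbation along a
    binary tree of depth ``lineage_depth``: the split below a node at tree
    level L adds independent N(0, (divergence * level_decay**L)^2) offsets
    to each child's logit profile.  Divergence therefore shrinks toward the
    leaves (``level_decay`` < 1), mirroring haematopoietic methylomes where
    the major-lineage split (lymphoid vs myeloid) dwarfs terminal splits
    (CD4T vs CD8T are nearly identical); siblings end up far more alike
    than cousins.  The first ``n_celltypes`` leaves become cell types; bulk
    samples are proportion-weighted mixtures of the reference betas plus
    N(0, noise_sd) measurement noise, clipped to the open unit interval.
    Proportions ~ Dirichlet(alpha) are stored both in the truth and as
    pheno columns (one per cell type).
    """
    _check_dims(n_samples, n_cpgs)
    if n_celltypes < 1 or n_celltypes > 2 ** lineage_depth:
        raise ConfigError(
            f"n_celltypes={n_celltypes} must be in [1, 2^{lineage_depth}]"
        )
    alpha = np.asarray(
        [dirichlet_alpha] * n_celltypes if np.isscalar(dirichlet_alpha) else dirichlet_alpha,
        dtype=float,
    )
    if alpha.shape != (n_celltypes,) or (alpha <= 0).any():
        raise ConfigError(f"invalid dirichlet alpha {dirichlet_alpha!r}")
    rng = np.random.default_rng(seed)

    cpg_ids = _ids("cg", n_cpgs)
    sample_ids = _ids("s", n_samples)

    # binary tree: node 0 is root; children of node i are 2i+1, 2i+2
    n_nodes = 2 ** (lineage_depth + 1) - 1
    logits = np.zeros((n_nodes, n_cpgs))
    logits[0] = _baseline_logits(rng, n_cpgs)
    parent = [-1] * n_nodes
    for i in range(n_nodes):
        level = int(np.floor(np.log2(i + 1)))
        scale = divergence * level_decay ** level
        for child in (2 * i + 1, 2 * i + 2):
            if child < n_nodes:
                parent[child] = i
                logits[child] = logits[i] + scale * rng.standard_normal(n_cpgs)

    first_leaf = 2 ** lineage_depth - 1
    leaf_idx = np.arange(first_leaf, first_leaf + n_celltypes)
    references = _sigmoid(logits[leaf_idx])
    cell_types = _ids("ct", n_celltypes)

    if n_celltypes == 1:
        proportions = np.ones((n_samples, 1))
    else:
        proportions = rng.dirichlet(alpha, size=n_samples)

    beta = proportions @ references + noise_sd * rng.standard_normal((n_samples, n_cpgs))
    beta = np.clip(beta, 1e-6, 1.0 - 1e-6)

    prop_df = pd.DataFrame(proportions, index=sample_ids, columns=cell_types)
    arr = MethylationArray(
        pd.DataFrame(beta, index=sample_ids, columns=cpg_ids),
        prop_df.copy(),
        validate=False,
    )
    truth = SyntheticTruth(
        seed=seed,
        proportions=prop_df,
        lineage=parent,
        references=pd.DataFrame(references, index=cell_types, columns=cpg_ids),
    )
    return arr, truth


def generate_exposure_dataset(
    n_samples: int = 200,
    n_cpgs: int = 500,
    n_informative: int = 50,
    effect_decay: float = 0.9,
    noise_sd: float = 0.5,
    seed: int = 0,
    max_effect: float = 2.0,
) -> tuple[MethylationArray, SyntheticTruth]:
    """Binary exposure with geometrically decaying effect sizes.

    The exposure (pheno column ``"exposure"``, values "exposed"/"control")
    is balanced.  Informative CpG r (1-based rank) is shifted by
    ``max_effect * effect_decay**(r-1)`` logit units in exposed samples,
    with random sign, so a planted importance ranking exists: sorting the
    stored effects by magnitude recovers rank order exactly.
    """
    _check_dims(n_samples, n_cpgs, n_informative)
    if effect_decay <= 0:
        raise ConfigError(f"effect_decay must be positive, got {effect_decay}")
    rng = np.random.default_rng(seed)

    cpg_ids = _ids("cg", n_cpgs)
    sample_ids = _ids("s", n_samples)
    baseline = _baseline_logits(rng, n_cpgs)

    exposure = np.zeros(n_samples, dtype=int)
    exposure[: n_samples // 2] = 1
    exposure = exposure[rng.permutation(n_samples)]

    informative = rng.choice(n_cpgs, size=n_informative, replace=False)
    magnitudes = max_effect * effect_decay ** np.arange(n_informative)
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    effects = np.zeros(n_cpgs)
    effects[informative] = magnitudes * signs

    logits = (
        baseline[None, :]
        + np.outer(exposure.astype(float), effects)
        + noise_sd * rng.standard_normal((n_samples, n_cpgs))
    )
    beta = _sigmoid(logits)

    arr = MethylationArray(
        pd.DataFrame(beta, index=sample_ids, columns=cpg_ids),
        pd.DataFrame(
            {"exposure": np.where(exposure == 1, "exposed", "control")},
            index=sample_ids,
        ),
        validate=False,
    )
    truth = SyntheticTruth(
        seed=seed,
        class_labels=arr.pheno["exposure"],
        effect_cpgs={"exposure": {cpg_ids[j]: float(effects[j]) for j in informative}},
    )
    return arr, truth
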