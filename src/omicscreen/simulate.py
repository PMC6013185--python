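"""Synthetic two-group omics datasets with block-correlated features.

The generator draws per-feature baseline means from a gamma distribution,
then samples feature intensities from a multivariate normal whose covariance
is block diagonal: three compound-symmetry blocks of correlated features
(constant within-block correlation ``rho``) followed by a block of
independent noise features.  A fixed number of features per correlated block
carry a group-mean shift ("differential" features); the remaining features
in those blocks are correlated with the differential ones but have no mean
shift of their own ("correlated non-null"), and the noise features are the
truly independent nulls used to measure Type I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ScenarioSpec",
    "FeatureTruth",
    "SimulatedDataset",
    "draw_feature_means",
    "build_block_structure",
    "simulate_dataset",
]

CATEGORY_DIFFERENTIAL = "differential"
CATEGORY_CORRELATED = "correlated_nonnull"
CATEGORY_NOISE = "noise"


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete parameterization of one simulation scenario.

    Parameters
    ----------
    block_size
        Number of features in each of the three correlated blocks
        (35 or 350 in the standard grid).
    noise_count
        Number of independent noise features (100 or 1000).
    rho
        Compound-symmetry correlation within each correlated block,
        in ``[0, 1)``.
    n_total
        Total number of samples across the two groups.
    deltas
        Group-mean difference (Cohen's d scale, since the residual SD is 1)
        for the differential features of each correlated block.
    n_diff_per_block
        Differential features per correlated block (the first
        ``n_diff_per_block`` indices of each block carry the shift).
    sigma2
        Common diagonal variance of the multivariate normal.
    gamma_shape, gamma_scale
        Shape ``kappa`` and scale ``theta`` of the gamma distribution the
        baseline feature means are drawn from (defaults give mean
        ``kappa * theta = 1`` and variance ``kappa * theta**2 = 1/50``).
    group_sizes
        Sizes of group 1 and group 2; balanced ``n_total/2`` each by default.
    seed
        Base seed used when the scenario is simulated without an explicit
        random generator.
    """

    block_size: int = 35
    noise_count: int = 100
    rho: float = 0.4
    n_total: int = 10
    deltas: tuple[float, ...] = (0.2, 0.5, 0.8)
    n_diff_per_block: int = 4
    sigma2: float = 1.0
    gamma_shape: float = 50.0
    gamma_scale: float = 1.0 / 50.0
    group_sizes: tuple[int, int] | None = None
    seed: int = 0
    n_correlated_blocks: int = field(default=3, init=False)

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.noise_count < 0:
            raise ValueError("noise_count must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(
                f"rho must be in [0, 1) for a positive-definite "
                f"compound-symmetry block, got {self.rho}"
            )
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if len(self.deltas) != self.n_correlated_blocks:
            raise ValueError(
                f"need one delta per correlated block "
                f"({self.n_correlated_blocks}), got {len(self.deltas)}"
            )
        if not 0 <= self.n_diff_per_block <= self.block_size:
            raise ValueError("n_diff_per_block must be in [0, block_size]")
        if self.group_sizes is None:
            if self.n_total % 2 != 0:
                raise ValueError(
                    f"n_total={self.n_total} is odd; balanced groups need an "
                    f"even total (or pass group_sizes explicitly)"
                )
            object.__setattr__(
                self, "group_sizes", (self.n_total // 2, self.n_total // 2)
            )
        else:
            n1, n2 = self.group_sizes
            if n1 <= 0 or n2 <= 0:
                raise ValueError("group sizes must be positive")
            if n1 + n2 != self.n_total:
                raise ValueError(
                    f"group_sizes {self.group_sizes} do not sum to "
                    f"n_total={self.n_total}"
                )

    @property
    def p(self) -> int:
        """Total number of features."""
        return self.n_correlated_blocks * self.block_size + self.noise_count

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("n_correlated_blocks")
        d["deltas"] = list(d["deltas"])
        d["group_sizes"] = list(d["group_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        if "deltas" in d:
            d["deltas"] = tuple(d["deltas"])
        if d.get("group_sizes") is not None:
            d["group_sizes"] = tuple(d["group_sizes"])
        return cls(**d)

    @property
    def scenario_id(self) -> str:
        return f"p{self.p}_rho{self.rho:g}_n{self.n_total}"


@dataclass(frozen=True)
class FeatureTruth:
    """Ground-truth annotation of every simulated feature.

    ``category[i]`` is one of ``differential``, ``correlated_nonnull`` or
    ``noise``; ``block_id[i]`` is 1..3 for features inside a correlated
    block and 0 for noise; ``effect_size[i]`` is the group-mean shift of a
    differential feature and 0 otherwise.
    """

    category: np.ndarray
    block_id: np.ndarray
    effect_size: np.ndarray

    @property
    def p(self) -> int:
        return self.category.shape[0]

    def counts(self) -> dict[str, int]:
        cats, n = np.unique(self.category, return_counts=True)
        return dict(zip(cats.tolist(), n.tolist()))


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated dataset: intensities, group labels and ground truth."""

    values: np.ndarray  # samples x features
    labels: np.ndarray  # group indicator in {1, 2} per sample
    truth: FeatureTruth
    means: np.ndarray  # baseline mean per feature
    spec: ScenarioSpec

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def draw_feature_means(
    p: int, shape: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``p`` i.i.d. gamma(shape, scale) baseline feature means."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    return rng.gamma(shape=shape, scale=scale, size=p)


def build_block_structure(spec: ScenarioSpec) -> FeatureTruth:
    """Deterministic feature layout for a scenario.

    Blocks 1-3 occupy consecutive index ranges of ``block_size`` features
    each, followed by the independent noise features.  The first
    ``n_diff_per_block`` features of each correlated block are flagged
    differential with that block's effect size.  Features within a block are
    exchangeable under the model, so fixing the differential indices loses
    no generality.
    """
    p = spec.p
    category = np.full(p, CATEGORY_NOISE, dtype=object)
    block_id = np.zeros(p, dtype=int)
    effect = np.zeros(p, dtype=float)
    for b in range(spec.n_correlated_blocks):
        lo = b * spec.block_size
        hi = lo + spec.block_size
        category[lo:hi] = CATEGORY_CORRELATED
        block_id[lo:hi] = b + 1
        category[lo : lo + spec.n_diff_per_block] = CATEGORY_DIFFERENTIAL
        effect[lo : lo + spec.n_diff_per_block] = spec.deltas[b]
    return FeatureTruth(
        category=np.asarray(category, dtype=object),
        block_id=block_id,
        effect_size=effect,
    )


def simulate_dataset(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Simulate one dataset under ``spec``.

    Baseline means are gamma draws; each correlated block is sampled from a
    multivariate normal with compound-symmetry covariance
    ``sigma2 * ((1 - rho) I + rho J)`` using the one-factor representation
    ``x = sqrt(rho) z + sqrt(1 - rho) e`` with a shared standard normal ``z``
    per (sample, block) — exactly equivalent to a Cholesky draw of the block
    and never materializes the full p x p covariance.  Noise features are
    i.i.d. normal.  Differential features get ``+delta`` added to the
    group-2 mean (the direction is a convention; only the difference is
    specified by the model).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = build_block_structure(spec)
    p, n = spec.p, spec.n_total
    mu = draw_feature_means(p, spec.gamma_shape, spec.gamma_scale, rng)
    sigma = float(np.sqrt(spec.sigma2))

    values = np.empty((n, p), dtype=np.float64)
    for b in range(spec.n_correlated_blocks):
        lo = b * spec.block_size
        hi = lo + spec.block_size
        shared = rng.standard_normal((n, 1))
        indiv = rng.standard_normal((n, spec.block_size))
        values[:, lo:hi] = sigma * (
            np.sqrt(spec.rho) * shared + np.sqrt(1.0 - spec.rho) * indiv
        )
    noise_lo = spec.n_correlated_blocks * spec.block_size
    if spec.noise_count:
        values[:, noise_lo:] = sigma * rng.standard_normal(
            (n, spec.noise_count)
        )
    values += mu[None, :]

    n1, n2 = spec.group_sizes
    labels = np.concatenate(
        [np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)]
    )
    diff = truth.effect_size != 0
    values[np.ix_(labels == 2, diff)] += truth.effect_size[diff][None, :]

    return SimulatedDataset(
        values=values, labels=labels, truth=truth, means=mu, spec=spec
    )
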