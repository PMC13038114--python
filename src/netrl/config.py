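"""Run configuration shared by the pipeline, benchmark and CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]

_CRITERIA = ("perm", "hyper", "ci", "none")
_VARIANTS = ("beta", "corr", "prior", "none")
_AGGREGATIONS = ("mean", "median")


@dataclass
class RunConfig:
    """Tunable parameters of a netRL run.

    Parameters
    ----------
    omega
        Number of bootstrap replicates per stage (the ensemble size).
    p1_star, p2_star
        Candidate-set sizes for the importance and estimation stages;
        ``None`` means half the regulator universe (rounded up).
    pi_reps
        Number of permutation replicates for the permutation edge test.
    alpha
        Significance level for all edge-selection criteria.
    criterion
        Edge-selection rule: ``perm`` (permutation p-value), ``hyper``
        (hypergeometric tail), ``ci`` (percentile bootstrap interval) or
        ``none`` (keep every nonzero aggregated coefficient above
        ``coef_threshold``).
    adjacency_variant
        Source of the gene graph behind centralities and the Laplacian
        penalty: ``beta`` (averaged stage-1 coefficients), ``corr``
        (absolute correlation), ``prior`` (user-supplied graph) or
        ``none`` (no graph: uniform centrality weight and no Laplacian
        penalty, i.e. the plain random lasso).
    aggregation
        ``mean`` or ``median`` of the replicate coefficients (zeros
        included for replicates that did not sample a gene).
    lambda1_count, lambda1_min_ratio, lambda2_values
        The within-replicate BIC grid: log-spaced L1 penalties from the
        critical value down, crossed with the Laplacian penalty weights.
    importance_floor
        Relative floor (times max importance) given to zero-importance
        genes so that sampling without replacement stays feasible.
    coef_threshold
        Magnitude below which aggregated coefficients are treated as
        zero by the ``none`` criterion.
    binarize_threshold
        Weight threshold when binarizing the gene graph for centralities.
    sigma2
        Optional fixed noise variance for the BIC; estimated per dataset
        when ``None``.
    n_boot
        Bootstrap sample size; the full sample size when ``None``.  In
        two-group analyses the caller sets this to min(nS, nN).
    adjacency_omega
        Bootstrap replicates per auxiliary target when sweeping the
        coefficient adjacency; defaults to ``omega``.
    """

    omega: int = 200
    p1_star: int | None = None
    p2_star: int | None = None
    pi_reps: int = 100
    alpha: float = 0.05
    criterion: str = "perm"
    adjacency_variant: str = "beta"
    aggregation: str = "mean"
    lambda1_count: int = 30
    lambda1_min_ratio: float = 0.01
    lambda2_values: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0)
    importance_floor: float = 1e-6
    coef_threshold: float = 0.0
    binarize_threshold: float = 0.0
    sigma2: float | None = None
    n_boot: int | None = None
    adjacency_omega: int | None = None
    cd_tol: float = 1e-5
    max_iter: int = 10_000
    seed: int | None = None
    group_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValueError("omega must be at least 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.criterion not in _CRITERIA:
            raise ValueError(f"criterion must be one of {_CRITERIA}")
        if self.adjacency_variant not in _VARIANTS:
            raise ValueError(f"adjacency_variant must be one of {_VARIANTS}")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
        if self.pi_reps < 1:
            raise ValueError("pi_reps must be at least 1")
        if any(v < 0 for v in self.lambda2_values):
            raise ValueError("lambda2 values must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["lambda2_values"] = list(d["lambda2_values"])
        d["group_labels"] = list(d["group_labels"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "lambda2_values" in d:
            d["lambda2_values"] = tuple(d["lambda2_values"])
        if "group_labels" in d:
            d["group_labels"] = tuple(d["group_labels"])
        return cls(**d)
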