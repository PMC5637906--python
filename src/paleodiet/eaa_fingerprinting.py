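"""Essential amino acid delta-13C fingerprinting and Bayesian source mixing.

Essential amino acids (EAAs) are routed from diet to consumer collagen with
minimal carbon isotope fractionation, so the *pattern* of delta-13C values
across EAAs fingerprints the protein source independently of absolute
baseline values.  The workflow is:

1. center each sample's EAA delta-13C values to their sample mean
   (:func:`center_pattern`);
2. ordinate the training samples by PCA (:func:`pca_scores`) and group them
   into candidate food groups — grouping is an explicit, user-supplied
   assignment, never automatic;
3. summarize each group's centered pattern (:func:`build_source_groups`);
4. estimate the posterior source proportions of a consumer
   (:func:`fit_mixture`) under a flat Dirichlet prior and a Gaussian
   likelihood per EAA whose variance is the sum of the consumer's analytical
   variance, the proportion-weighted source variance, and a configurable
   model-error variance.

The sampler is a seeded random-walk Metropolis on the simplex via the
additive-log-ratio (logistic-normal) transform, run as several independent
chains with split R-hat convergence monitoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from paleodiet.data_model import IsotopeValue, ValidationError

#: EAA set used for fingerprinting; Lys takes part in centering and PCA but
#: is excluded from the default mixing likelihood as least source-diagnostic.
EAA_SET = ("Leu", "Lys", "Phe", "Val")
DEFAULT_MIXING_EAAS = ("Leu", "Phe", "Val")

#: Canonical four food groups resolved by the training data.
SOURCE_GROUPS = ("Marine-I", "Marine-II", "Plant-I", "Plant-II")
MARINE_GROUPS = ("Marine-I", "Marine-II")


@dataclass(frozen=True)
class EAAPattern:
    """Per-sample EAA delta-13C pattern, optionally sample-mean centered."""

    sample_id: str
    values: Mapping[str, IsotopeValue]
    centered: bool = False
    #: the EAA set over which the pattern was centered (None if raw)
    center_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for aa in self.values:
            if aa not in EAA_SET:
                raise ValidationError(f"{self.sample_id}: {aa!r} is not a fingerprint EAA")
        if self.centered:
            included = [self.values[aa].mean for aa in (self.center_set or ())]
            if self.center_set is None or abs(sum(included)) > 1e-9:
                raise ValidationError(
                    f"{self.sample_id}: centered pattern does not sum to zero"
                )


def center_pattern(raw: EAAPattern, include: Sequence[str] = EAA_SET) -> EAAPattern:
    """Subtract the mean over ``include`` from each included EAA value.

    Centering removes the absolute baseline, leaving only the relative
    pattern; it is idempotent.  A missing EAA is a hard error naming it.
    """
    include = tuple(include)
    for aa in include:
        if aa not in raw.values:
            raise ValidationError(f"{raw.sample_id}: missing EAA {aa!r} for centering")
    mean = sum(raw.values[aa].mean for aa in include) / len(include)
    values = {
        aa: IsotopeValue(v.mean - mean, v.sd, v.n) if aa in include else v
        for aa, v in raw.values.items()
    }
    return EAAPattern(raw.sample_id, values, centered=True, center_set=include)


# ---------------------------------------------------------------------------
# PCA ordination


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # components x EAAs
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def _pattern_matrix(
    patterns: Sequence[EAAPattern], include: tuple[str, ...]
) -> np.ndarray:
    for p in patterns:
        if not p.centered:
            raise ValidationError(f"{p.sample_id}: pattern is not centered")
        if p.center_set != include:
            raise ValidationError(
                f"{p.sample_id}: centered over {p.center_set}, expected {include}"
            )
    return np.array([[p.values[aa].mean for aa in include] for p in patterns])


def pca_scores(
    training: Sequence[EAAPattern], include: Sequence[str] = EAA_SET
) -> PCAResult:
    """PCA of mean-centered EAA patterns, deterministic up to documented sign.

    Component sign is fixed by making each loading vector's
    largest-magnitude element positive.  Components with numerically zero
    variance (the centering constraint removes one degree of freedom) are
    dropped with a warning.
    """
    include = tuple(include)
    if len(training) < 3:
        raise ValidationError("PCA requires at least 3 training patterns")
    x = _pattern_matrix(training, include)
    n_comp = min(x.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)

    keep = pca.explained_variance_ > 1e-10 * max(pca.explained_variance_.sum(), 1e-30)
    if not keep.all():
        warnings.warn(
            f"rank-deficient input: keeping {int(keep.sum())} of {n_comp} components",
            stacklevel=2,
        )
    components = pca.components_[keep]
    scores = scores[:, keep]
    # sign convention: largest-magnitude loading positive
    for j, row in enumerate(components):
        if row[np.argmax(np.abs(row))] < 0:
            components[j] = -row
            scores[:, j] = -scores[:, j]
    names = [f"PC{j + 1}" for j in range(scores.shape[1])]
    ids = [p.sample_id for p in training]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ids, columns=names),
        loadings=pd.DataFrame(components, index=names, columns=list(include)),
        explained_variance=pca.explained_variance_[keep],
        explained_variance_ratio=pca.explained_variance_ratio_[keep],
    )


# ---------------------------------------------------------------------------
# source groups


@dataclass(frozen=True)
class SourceGroup:
    """Per-EAA mean/SD of centered delta-13C for one candidate food group."""

    name: str
    member_ids: tuple[str, ...]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    center_set: tuple[str, ...]


def build_source_groups(
    training: Sequence[EAAPattern], assignment: Mapping[str, str]
) -> list[SourceGroup]:
    """Summarize centered training patterns into per-group mean/SD patterns.

    ``assignment`` maps every training sample id to a group label; an
    unknown id is an error.  Single-member groups get SD 0.
    """
    by_id = {p.sample_id: p for p in training}
    unknown = set(assignment) - set(by_id)
    if unknown:
        raise ValidationError(f"assignment references unknown sample ids: {sorted(unknown)}")
    unassigned = set(by_id) - set(assignment)
    if unassigned:
        raise ValidationError(f"training samples without assignment: {sorted(unassigned)}")

    center_sets = {p.center_set for p in training}
    if len(center_sets) != 1 or None in center_sets:
        raise ValidationError("all training patterns must be centered over one EAA set")
    include = center_sets.pop()

    groups: dict[str, list[EAAPattern]] = {}
    for sid, label in assignment.items():
        groups.setdefault(label, []).append(by_id[sid])

    out = []
    for label in sorted(groups):
        members = sorted(groups[label], key=lambda p: p.sample_id)
        mat = np.array([[p.values[aa].mean for aa in include] for p in members])
        means = dict(zip(include, mat.mean(axis=0)))
        sds = dict(
            zip(include, mat.std(axis=0, ddof=1) if len(members) > 1 else np.zeros(mat.shape[1]))
        )
        out.append(
            SourceGroup(
                name=label,
                member_ids=tuple(p.sample_id for p in members),
                means=means,
                sds=sds,
                center_set=include,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bayesian mixing


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration; the seed is mandatory for reproducibility."""

    seed: int = 0
    n_chains: int = 4
    n_steps: int = 3000
    burn: int = 1000
    step_size: float = 0.6
    #: residual model-error SD (permil) added to every EAA's likelihood
    #: variance; defaults to the analytical replicate scale.
    model_error_sd: float = 0.4
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 4:
            raise ValidationError("at least 4 chains are required for diagnostics")
        if not 0 < self.burn < self.n_steps:
            raise ValidationError("require 0 < burn < n_steps")


@dataclass(frozen=True)
class MixturePosterior:
    """Posterior draws over source proportion vectors with summaries."""

    source_names: tuple[str, ...]
    draws: np.ndarray               # (n_draws, n_sources); each row sums to 1
    summary: pd.DataFrame           # mean, sd, 68% and 95% credible intervals
    diagnostics: dict
    converged: bool


def _split_rhat(chains: np.ndarray) -> float:
    """Split R-hat of one scalar quantity; ``chains`` is (n_chains, n_draws)."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _ess(chains: np.ndarray) -> float:
    """Crude effective sample size from pooled autocorrelation (initial
    positive sequence estimator)."""
    m, n = chains.shape
    centered = chains - chains.mean(axis=1, keepdims=True)
    var = centered.var(axis=1).mean()
    if var == 0:
        return float(m * n)
    rho_sum = 0.0
    for lag in range(1, n):
        rho = np.mean(
            [np.dot(c[:-lag], c[lag:]) / n for c in centered]
        ) / var
        if rho < 0.05:
            break
        rho_sum += rho
    return float(m * n / (1.0 + 2.0 * rho_sum))


def fit_mixture(
    consumer: EAAPattern,
    sources: Sequence[SourceGroup],
    use_eaas: Sequence[str] = DEFAULT_MIXING_EAAS,
    mcmc: MCMCConfig | None = None,
) -> MixturePosterior:
    """Posterior source proportions for a centered consumer pattern.

    Model: proportions p ~ flat Dirichlet; for each used EAA k the observed
    centered value is Normal(sum_i p_i mu_ik, sigma_k^2) with sigma_k^2 the
    consumer analytical variance plus the proportion-weighted source
    variance (sum_i p_i^2 s_ik^2) plus the model-error variance.  Sampling is
    random-walk Metropolis in additive-log-ratio coordinates; with a fixed
    seed the result is bit-identical across runs.  Non-convergence (split
    R-hat above threshold) is flagged on the result, never silent.
    """
    mcmc = mcmc or MCMCConfig()
    sources = list(sources)
    if len(sources) < 2:
        raise ValidationError("at least 2 sources are required")
    use_eaas = tuple(use_eaas)
    if not consumer.centered:
        raise ValidationError(f"{consumer.sample_id}: consumer pattern is not centered")
    for s in sources:
        if s.center_set != consumer.center_set:
            raise ValidationError(
                f"source {s.name!r} centered over {s.center_set}, "
                f"consumer over {consumer.center_set}"
            )
    for aa in use_eaas:
        if aa not in consumer.values:
            raise ValidationError(f"consumer lacks EAA {aa!r}")
        for s in sources:
            if aa not in s.means:
                raise ValidationError(f"source {s.name!r} lacks EAA {aa!r}")

    k = len(sources)
    mu = np.array([[s.means[aa] for aa in use_eaas] for s in sources])       # (k, m)
    src_var = np.array([[s.sds[aa] ** 2 for aa in use_eaas] for s in sources])
    obs = np.array([consumer.values[aa].mean for aa in use_eaas])
    base_var = (
        np.array([consumer.values[aa].sd ** 2 for aa in use_eaas])
        + mcmc.model_error_sd**2
    )
    if np.any(base_var <= 0):
        raise ValidationError("zero total likelihood variance; supply model_error_sd > 0")

    def log_post(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """z is (c, k-1) ALR coordinates -> (log posterior, proportions)."""
        full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        p = e / e.sum(axis=1, keepdims=True)
        mean = p @ mu                                   # (c, m)
        var = base_var + (p**2) @ src_var               # (c, m)
        ll = -0.5 * np.sum((obs - mean) ** 2 / var + np.log(var), axis=1)
        jac = np.sum(np.log(np.clip(p, 1e-300, None)), axis=1)
        return ll + jac, p

    rng = np.random.default_rng(mcmc.seed)
    c = mcmc.n_chains
    z = rng.normal(scale=0.1, size=(c, k - 1))
    lp, p = log_post(z)
    step = mcmc.step_size
    kept: list[np.ndarray] = []
    n_accept = 0
    n_prop = 0
    for it in range(mcmc.n_steps):
        prop = z + step * rng.normal(size=(c, k - 1))
        lp_prop, p_prop = log_post(prop)
        accept = np.log(rng.random(c)) < lp_prop - lp
        z[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        p[accept] = p_prop[accept]
        if it < mcmc.burn:
            # Robbins-Monro adaptation toward ~30% acceptance, frozen after burn-in
            step *= math.exp(0.02 * (accept.mean() - 0.3))
        else:
            n_accept += int(accept.sum())
            n_prop += c
            kept.append(p.copy())

    draws_by_chain = np.stack(kept, axis=1)             # (chains, draws, k)
    rhat = np.array([_split_rhat(draws_by_chain[:, :, j]) for j in range(k)])
    ess = np.array([_ess(draws_by_chain[:, :, j]) for j in range(k)])
    converged = bool(np.all(rhat < mcmc.rhat_threshold))
    if not converged:
        warnings.warn(
            f"mixture sampler did not converge (max split R-hat {rhat.max():.3f})",
            stacklevel=2,
        )

    draws = draws_by_chain.reshape(-1, k)
    names = tuple(s.name for s in sources)
    q = np.quantile(draws, [0.025, 0.16, 0.84, 0.975], axis=0)
    summary = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "ci68_lo": q[1],
            "ci68_hi": q[2],
            "ci95_lo": q[0],
            "ci95_hi": q[3],
        },
        index=list(names),
    )
    diagnostics = {
        "rhat": dict(zip(names, rhat)),
        "ess": dict(zip(names, ess)),
        "acceptance": n_accept / max(n_prop, 1),
        "step_size": step,
        "n_draws": draws.shape[0],
    }
    return MixturePosterior(
        source_names=names,
        draws=draws,
        summary=summary,
        diagnostics=diagnostics,
        converged=converged,
    )


def aggregate_marine(
    post: MixturePosterior, marine_labels: Iterable[str] = MARINE_GROUPS
) -> dict:
    """Draw-wise sum of the marine source proportions, then summaries."""
    labels = [l for l in marine_labels]
    if not labels:
        raise ValidationError("empty marine label set")
    unknown = set(labels) - set(post.source_names)
    if unknown:
        raise ValidationError(f"unknown source labels: {sorted(unknown)}")
    idx = [post.source_names.index(l) for l in labels]
    total = post.draws[:, idx].sum(axis=1)
    q = np.quantile(total, [0.025, 0.16, 0.84, 0.975])
    return {
        "mean": float(total.mean()),
        "sd": float(total.std(ddof=1)),
        "ci68": (float(q[1]), float(q[2])),
        "ci95": (float(q[0]), float(q[3])),
    }
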