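"""Sequential Bayesian ranking of candidate kinases per phosphosite cluster.

Starting from a uniform prior over the kinase registry (1/N each, N = 521
for the reference mammalian kinome), Bayes' Rule is applied seven times,
once per evidence layer:

1–3. expression of the kinase in the tissue (one transcriptomic and two
     proteomic abundance tables),
4.   preference of the kinase for the cluster's phosphoacceptor (dot
     product of S/T/Y frequency triples, pivot 1/9),
5.   colocalization (dot product of subcellular fractionation profiles),
6.   curated activity direction versus the cluster's 15-min direction
     (discrete likelihoods 0.9 match / 0.1 mismatch / 0.7 regulated with
     unknown direction / 0.5 no data),
7.   motif match (dot product of information-content matrices at the
     cluster's signature positions).

Continuous evidence scores x are converted to likelihoods with the
complement of the minimum Bayes factor, cMBF = 1 - exp(-z*^2/2) with
z* = x / pivot, where the pivot parameter is the intrinsic noise scale of
the dataset (or the estimated Poisson rate of the scores).  Likelihoods
below 0.5 are reset to 0.5 ("coin flip") so a kinase missing from any one
table is never eliminated outright; the discrete step-6 values are exempt
so the 0.1 mismatch penalty keeps its meaning.  Because the update is
multiplicative, the final posterior is invariant to step order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import KinaseRegistry, PhosphoSite
from .clustering import frequency_matrix

logger = logging.getLogger("kinbayes")

LIKELIHOOD_FLOOR = 0.5
STY_PIVOT = 1.0 / 9.0

#: discrete step-6 likelihoods per annotation x direction case
ACTIVITY_MATCH = 0.9
ACTIVITY_MISMATCH = 0.1
ACTIVITY_UNKNOWN_DIRECTION = 0.7
ACTIVITY_NO_DATA = 0.5

#: default signature window positions per cluster branch, overridable
DEFAULT_SELECTED_POSITIONS: dict[str, tuple[int, ...]] = {
    "I": (1,),
    "II.A": (-3, -2),
    "II.B": (-3,),
    "III": (-3, -2),
    "IV": (-2, -1),
}

STEP_NAMES = (
    "transcript", "protein_a", "protein_b", "sty",
    "colocalization", "activity", "motif",
)


class ConfigurationError(ValueError):
    """The evidence bundle is missing a required step input."""


# ---------------------------------------------------------------------------
# Vectors and bundle types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinaseVector:
    """A per-kinase value vector aligned to the registry order."""

    values: pd.Series
    kind: str  # prior | likelihood | posterior

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if self.kind in ("prior", "posterior"):
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.kind} must sum to 1, got {v.sum()}")
            if (v < 0).any():
                raise ValueError(f"{self.kind} must be non-negative")
        elif self.kind == "likelihood":
            if (v < 0).any() or (v > 1).any():
                raise ValueError("likelihood values must lie in [0, 1]")
        else:
            raise ValueError(f"unknown vector kind {self.kind!r}")

    @classmethod
    def uniform_prior(cls, registry: KinaseRegistry) -> "KinaseVector":
        n = len(registry)
        return cls(pd.Series(1.0 / n, index=list(registry.kinases)), "prior")

    @classmethod
    def likelihood(cls, values: pd.Series) -> "KinaseVector":
        return cls(values, "likelihood")


@dataclass(frozen=True)
class PivotEstimate:
    """A cMBF pivot: fixed, or the Poisson rate estimated from the scores."""

    method: str  # fixed | poisson_rate
    value: float
    rate_lambda: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"pivot must be positive, got {self.value}")


@dataclass(frozen=True)
class LikelihoodSpec:
    """Record of one Bayesian step: scores, pivot and resulting z*."""

    step_id: int
    name: str
    data_values: pd.Series
    pivot: float
    floor: float | None

    @property
    def z_star(self) -> pd.Series:
        return self.data_values / self.pivot


@dataclass(frozen=True)
class ActivityAnnotation:
    """Curated net activity direction per kinase under the stimulus."""

    labels: dict[str, str]

    _ALLOWED = frozenset({"increase", "decrease", "regulated_unknown", "none"})

    def __post_init__(self) -> None:
        bad = set(self.labels.values()) - self._ALLOWED
        if bad:
            raise ValueError(f"unknown activity label(s): {sorted(bad)}")

    def label(self, kinase: str) -> str:
        return self.labels.get(kinase, "none")


@dataclass
class EvidenceBundle:
    """The per-step evidence tables plus pivot parameters.

    Tables are keyed by registry kinase symbols; missing kinases are
    handled by flooring (expression, colocalization) or nearest-neighbor
    interpolation (S/T/Y and motif preference).
    """

    transcript: pd.Series
    protein_a: pd.Series
    protein_b: pd.Series
    sty: pd.DataFrame                      # kinase x [f_S, f_T, f_Y]
    kinase_profiles: pd.DataFrame          # kinase x fraction
    substrate_profiles: pd.DataFrame       # gene symbol x fraction
    activity: ActivityAnnotation
    kinase_motifs: dict[str, pd.DataFrame]  # kinase -> position x residue freqs
    background: pd.Series                   # residue -> background frequency
    pivots: dict[str, object] = field(default_factory=dict)
    neighbor_map: dict[str, str] = field(default_factory=dict)
    selected_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def cmbf(z_star):
    """Complement of the minimum Bayes factor: 1 - exp(-z*^2 / 2).

    Symmetric in the sign of z*; maps 0 to 0 and grows to 1 as |z*| grows.
    """
    z = np.asarray(z_star, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z* must be finite")
    out = -np.expm1(-(z**2) / 2.0)
    return float(out) if np.isscalar(z_star) else out


def floor_likelihood(values, floor: float = LIKELIHOOD_FLOOR):
    """Elementwise max(value, floor); idempotent."""
    if isinstance(values, pd.Series):
        return values.clip(lower=floor)
    return np.maximum(np.asarray(values, dtype=float), floor)


def bayes_update(prior: KinaseVector, likelihood: KinaseVector) -> KinaseVector:
    """Posterior_i = L_i * prior_i / sum_j L_j * prior_j."""
    product = likelihood.values.reindex(prior.values.index) * prior.values
    total = product.sum()
    if total <= 0 or not np.isfinite(total):
        raise ZeroDivisionError("all prior x likelihood products are zero")
    return KinaseVector(product / total, "posterior")


def estimate_poisson_pivot(scores) -> PivotEstimate:
    """Pivot from the Poisson MLE (sample mean) of non-negative scores."""
    x = np.asarray(scores, dtype=float)
    if (x < 0).any():
        raise ValueError("Poisson-rate pivot needs non-negative scores")
    lam = float(x.mean()) if x.size else 0.0
    if lam == 0.0:
        raise ValueError("all-zero scores: Poisson rate undefined as a pivot")
    return PivotEstimate(method="poisson_rate", value=lam, rate_lambda=lam)


def interpolate_missing(
    scores: dict[str, float] | pd.Series,
    neighbor_map: dict[str, str],
    registry: KinaseRegistry,
) -> pd.Series:
    """Fill registry kinases absent from ``scores`` from their nearest neighbor.

    Chains of missing neighbors are walked; a cycle with no scored member,
    or a kinase with no neighbor at all, falls back to 0 with a warning.
    """
    known = dict(pd.Series(scores).items())
    out: dict[str, float] = {}
    for kinase in registry.kinases:
        if kinase in known:
            out[kinase] = float(known[kinase])
            continue
        seen = {kinase}
        current = kinase
        value = None
        while current in neighbor_map:
            current = neighbor_map[current]
            if current in known:
                value = float(known[current])
                break
            if current in seen:
                break  # cycle of unscored kinases
            seen.add(current)
        if value is None:
            logger.warning("kinase %s has no scored neighbor; score set to 0", kinase)
            value = 0.0
        out[kinase] = value
    return pd.Series(out, index=list(registry.kinases), dtype=float)


# ---------------------------------------------------------------------------
# Per-step likelihoods
# ---------------------------------------------------------------------------


def _floored_cmbf(scores: pd.Series, pivot: float) -> pd.Series:
    return pd.Series(
        floor_likelihood(cmbf((scores / pivot).to_numpy())), index=scores.index
    )


def expression_likelihood(
    values: pd.Series, pivot: float, registry: KinaseRegistry
) -> pd.Series:
    """Steps 1-3: cMBF of abundance / pivot; unmeasured kinases floor to 0.5."""
    if pivot <= 0:
        raise ValueError("expression pivot must be positive")
    v = values.reindex(list(registry.kinases)).fillna(0.0).astype(float)
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    return _floored_cmbf(v, pivot)


def sty_preference_likelihood(
    kinase_sty: pd.DataFrame,
    cluster_sty: np.ndarray,
    registry: KinaseRegistry,
    neighbor_map: dict[str, str] | None = None,
    pivot: float = STY_PIVOT,
) -> pd.Series:
    """Step 4: dot product of per-kinase and cluster (f_S, f_T, f_Y) triples.

    The 1/9 pivot keeps serine/threonine kinases nearly indistinguishable
    while still excluding tyrosine kinases from S/T clusters.
    """
    tri = np.asarray(cluster_sty, dtype=float)
    if (tri < 0).any() or (kinase_sty.to_numpy() < 0).any():
        raise ValueError("S/T/Y frequencies must be non-negative")
    scores = pd.Series(kinase_sty.to_numpy() @ tri, index=kinase_sty.index)
    scores = interpolate_missing(scores, neighbor_map or {}, registry)
    return _floored_cmbf(scores, pivot)


def colocalization_likelihood(
    kinase_profiles: pd.DataFrame,
    cluster_profile: pd.Series,
    registry: KinaseRegistry,
    pivot: PivotEstimate | float | None = None,
) -> tuple[pd.Series, PivotEstimate]:
    """Step 5: dot product of kinase and aggregate substrate fractionation profiles."""
    if not kinase_profiles.columns.equals(cluster_profile.index):
        if set(kinase_profiles.columns) != set(cluster_profile.index):
            raise ValueError("kinase and substrate profiles cover different fractions")
        cluster_profile = cluster_profile.reindex(kinase_profiles.columns)
    scores = pd.Series(
        kinase_profiles.to_numpy() @ cluster_profile.to_numpy(dtype=float),
        index=kinase_profiles.index,
    )
    scores = scores.reindex(list(registry.kinases)).fillna(0.0)
    if pivot is None:
        pivot = estimate_poisson_pivot(scores.to_numpy())
    elif not isinstance(pivot, PivotEstimate):
        pivot = PivotEstimate(method="fixed", value=float(pivot))
    return _floored_cmbf(scores, pivot.value), pivot


def activity_likelihood(
    annotation: ActivityAnnotation, cluster_direction: str, registry: KinaseRegistry
) -> pd.Series:
    """Step 6: discrete likelihoods from curated activity direction.

    match -> 0.9, mismatch -> 0.1, regulated with unknown direction -> 0.7,
    no data -> 0.5.  Not floored: the 0.1 penalty is an explicit assignment.
    """
    if cluster_direction not in ("increased", "decreased"):
        raise ValueError(f"direction must be increased/decreased, got "
                         f"{cluster_direction!r}")
    match_label = "increase" if cluster_direction == "increased" else "decrease"
    values = {}
    for kinase in registry.kinases:
        label = annotation.label(kinase)
        if label == "none":
            values[kinase] = ACTIVITY_NO_DATA
        elif label == "regulated_unknown":
            values[kinase] = ACTIVITY_UNKNOWN_DIRECTION
        elif label == match_label:
            values[kinase] = ACTIVITY_MATCH
        else:
            values[kinase] = ACTIVITY_MISMATCH
    return pd.Series(values, index=list(registry.kinases), dtype=float)


def information_content(freqs: pd.DataFrame, background: pd.Series) -> pd.DataFrame:
    """IC(a, i) = P(a, i) * log2(P(a, i) / P_ref(a)); zero frequency gives 0."""
    bg = background.reindex(freqs.columns)
    p = freqs.to_numpy(dtype=float)
    zero_bg = (bg.isna() | (bg == 0)).to_numpy()
    if (p[:, zero_bg] > 0).any():
        offenders = [
            str(a) for a, z in zip(freqs.columns, zero_bg) if z and (freqs[a] > 0).any()
        ]
        raise ValueError(
            f"background frequency is 0 for residue(s) {offenders} with P(a,i) > 0"
        )
    bgv = bg.fillna(1.0).to_numpy(dtype=float)
    bgv[bgv == 0] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = p * np.log2(p / bgv)
    ic[p == 0] = 0.0
    return pd.DataFrame(ic, index=freqs.index, columns=freqs.columns)


def motif_match_likelihood(
    kinase_ic: dict[str, pd.DataFrame],
    cluster_ic: pd.DataFrame,
    selected_positions: tuple[int, ...],
    registry: KinaseRegistry,
    neighbor_map: dict[str, str] | None = None,
    pivot: PivotEstimate | float | None = None,
) -> tuple[pd.Series, PivotEstimate]:
    """Step 7: dot product of IC matrices at the cluster's signature positions.

    Negative per-cell products (anti-motif agreement) are clipped to 0 so
    they cannot inflate the likelihood through the sign-symmetric cMBF.
    """
    if not selected_positions:
        raise ValueError("selected_positions must be non-empty")
    flank = (len(cluster_ic.index) - 1) // 2
    for p in selected_positions:
        if abs(p) > flank:
            raise ValueError(f"selected position {p} outside ±{flank}")
    scores = {}
    for kinase, kic in kinase_ic.items():
        total = 0.0
        for pos in selected_positions:
            if pos not in kic.index or pos not in cluster_ic.index:
                continue
            joint = kic.columns.intersection(cluster_ic.columns)
            prod = (
                kic.loc[pos, joint].to_numpy(dtype=float)
                * cluster_ic.loc[pos, joint].to_numpy(dtype=float)
            )
            total += np.maximum(prod, 0.0).sum()
        scores[kinase] = total
    series = interpolate_missing(pd.Series(scores), neighbor_map or {}, registry)
    if pivot is None:
        pivot = estimate_poisson_pivot(series.to_numpy())
    elif not isinstance(pivot, PivotEstimate):
        pivot = PivotEstimate(method="fixed", value=float(pivot))
    return _floored_cmbf(series, pivot.value), pivot


# ---------------------------------------------------------------------------
# Cluster summaries feeding the steps
# ---------------------------------------------------------------------------


def cluster_sty_frequencies(sites: list[PhosphoSite]) -> np.ndarray:
    """(f_S, f_T, f_Y) of the phosphoacceptors among cluster members."""
    n = len(sites)
    if n == 0:
        raise ValueError("empty cluster")
    return np.array(
        [sum(1 for s in sites if s.residue == aa) / n for aa in "STY"], dtype=float
    )


def cluster_profile(
    sites: list[PhosphoSite], substrate_profiles: pd.DataFrame
) -> pd.Series:
    """Mean fractionation profile over member proteins present in the table."""
    rows = [
        substrate_profiles.loc[s.gene_symbol]
        for s in sites
        if s.gene_symbol in substrate_profiles.index
    ]
    if not rows:
        return pd.Series(0.0, index=substrate_profiles.columns)
    return pd.concat(rows, axis=1).mean(axis=1)


def cluster_direction(sites: list[PhosphoSite]) -> str:
    """Majority 15-min direction of member sites; mean sign breaks ties."""
    last = np.array([s.timecourse.log2_ratio[-1] for s in sites], dtype=float)
    up, down = int((last > 0).sum()), int((last < 0).sum())
    if up != down:
        return "increased" if up > down else "decreased"
    total = last.sum()
    if total == 0:
        raise ValueError("cluster direction is an exact tie")
    return "increased" if total > 0 else "decreased"


def selected_positions_for(label: str,
                           overrides: dict[str, tuple[int, ...]] | None = None
                           ) -> tuple[int, ...]:
    """Signature positions for a cluster label, longest matching branch wins."""
    table = dict(DEFAULT_SELECTED_POSITIONS)
    if overrides:
        table.update(overrides)
    best = None
    for prefix in table:
        if label == prefix or label.startswith(prefix + "."):
            if best is None or len(prefix) > len(best):
                best = prefix
    if best is None:
        raise ValueError(f"no selected positions configured for cluster {label!r}")
    return tuple(table[best])


# ---------------------------------------------------------------------------
# The seven-step pipeline
# ---------------------------------------------------------------------------


def _resolve_pivot(bundle: EvidenceBundle, name: str, values: pd.Series) -> float:
    """Expression pivots come from config; default is the median positive value."""
    configured = bundle.pivots.get(name)
    if configured is not None:
        return float(configured)
    positive = values[values > 0]
    if positive.empty:
        raise ConfigurationError(f"no positive values to derive a pivot for {name}")
    return float(positive.median())


def run_pipeline(
    sites: list[PhosphoSite],
    cluster_label: str,
    bundle: EvidenceBundle,
    registry: KinaseRegistry,
    return_steps: bool = False,
):
    """Rank all registry kinases for one cluster through the seven steps.

    Returns a DataFrame (rank, kinase, family, posterior, probability_ratio)
    sorted by descending posterior with alphabetical tie-break; the
    probability ratio divides the posterior by the uniform initial prior
    1/N, so values above 1 mark kinases the evidence favors.
    """
    for attr in ("transcript", "protein_a", "protein_b", "sty", "kinase_profiles",
                 "substrate_profiles", "activity", "kinase_motifs", "background"):
        if getattr(bundle, attr, None) is None:
            raise ConfigurationError(f"evidence bundle is missing step input {attr!r}")
    if not sites:
        raise ValueError("cluster has no member sites")

    n = len(registry)
    prior = KinaseVector.uniform_prior(registry)
    steps: list[LikelihoodSpec] = []
    posterior = prior

    def apply(step_id: int, name: str, lik: pd.Series, pivot: float,
              floor: float | None) -> None:
        nonlocal posterior
        steps.append(LikelihoodSpec(step_id, name, lik, pivot, floor))
        posterior = bayes_update(posterior, KinaseVector.likelihood(lik))
        logger.debug("step %d (%s): top3 %s", step_id, name,
                     posterior.values.nlargest(3).round(4).to_dict())

    # steps 1-3: expression layers
    for step_id, name in ((1, "transcript"), (2, "protein_a"), (3, "protein_b")):
        values = getattr(bundle, name)
        pivot = _resolve_pivot(bundle, name, values)
        apply(step_id, name, expression_likelihood(values, pivot, registry),
              pivot, LIKELIHOOD_FLOOR)

    # step 4: phosphoacceptor preference
    sty_pivot = float(bundle.pivots.get("sty", STY_PIVOT))
    apply(4, "sty",
          sty_preference_likelihood(bundle.sty, cluster_sty_frequencies(sites),
                                    registry, bundle.neighbor_map, sty_pivot),
          sty_pivot, LIKELIHOOD_FLOOR)

    # step 5: colocalization
    coloc_pivot = bundle.pivots.get("colocalization")
    lik5, pivot5 = colocalization_likelihood(
        bundle.kinase_profiles, cluster_profile(sites, bundle.substrate_profiles),
        registry,
        None if coloc_pivot in (None, "poisson") else float(coloc_pivot),
    )
    apply(5, "colocalization", lik5, pivot5.value, LIKELIHOOD_FLOOR)

    # step 6: curated activity direction (discrete, not floored)
    direction = cluster_direction(sites)
    apply(6, "activity", activity_likelihood(bundle.activity, direction, registry),
          float("nan"), None)

    # step 7: motif match at the cluster's signature positions
    cluster_fm = frequency_matrix([s.window for s in sites])
    cluster_ic = information_content(cluster_fm.freqs, bundle.background)
    kinase_ic = {
        k: information_content(m, bundle.background)
        for k, m in bundle.kinase_motifs.items()
    }
    positions = selected_positions_for(cluster_label, bundle.selected_positions)
    motif_pivot = bundle.pivots.get("motif")
    lik7, pivot7 = motif_match_likelihood(
        kinase_ic, cluster_ic, positions, registry, bundle.neighbor_map,
        None if motif_pivot in (None, "poisson") else float(motif_pivot),
    )
    apply(7, "motif", lik7, pivot7.value, LIKELIHOOD_FLOOR)

    result = pd.DataFrame(
        {
            "kinase": posterior.values.index,
            "family": [registry.families.get(k, "") for k in posterior.values.index],
            "posterior": posterior.values.to_numpy(),
        }
    )
    result["probability_ratio"] = result["posterior"] * n
    result = result.sort_values(
        ["posterior", "kinase"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    result.insert(0, "rank", np.arange(1, len(result) + 1))
    if return_steps:
        return result, steps
    return result


def rank_all_clusters(
    sites: list[PhosphoSite],
    assignments,
    bundle: EvidenceBundle,
    registry: KinaseRegistry,
    min_cluster_size: int = 3,
) -> dict[str, pd.DataFrame]:
    """Run the pipeline for every leaf cluster with >= min_cluster_size members."""
    by_id = {s.site_id: s for s in sites}
    members: dict[str, list[PhosphoSite]] = {}
    for a in assignments:
        if a.leaf_label and not a.unassigned_flag and a.site_id in by_id:
            members.setdefault(a.leaf_label, []).append(by_id[a.site_id])
    rankings = {}
    for label in sorted(members):
        group = members[label]
        if len(group) < min_cluster_size:
            logger.info("skipping cluster %s: only %d member(s)", label, len(group))
            continue
        rankings[label] = run_pipeline(group, label, bundle, registry)
    return rankings
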