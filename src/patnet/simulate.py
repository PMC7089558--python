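"""Synthetic PAT cohorts via a latent-threshold (multivariate probit) model.

The study cohorts (acute lymphoblastic leukemia n=90, epilepsy n=42, asthma
n=63) are not publicly deposited, so every downstream stage is exercised on
simulated cohorts whose *marginal* structure is calibrated to the published
disease profiles:

* each item's risk prevalence defaults to its subscale's published mean score
  (the subscale score is the mean of its items, so the expected subscale score
  equals the mean item prevalence — an exact identity);
* published item-level prevalence anchors (e.g. mood changes reported for 80%
  of ALL families) override the default, and the remaining items on that
  subscale are renormalised so the subscale mean is preserved;
* dependence is a block-structured latent correlation: within each subscale a
  single correlation solved so that the model-implied subscale-score SD
  matches the published SD (falling back to 0.4 where no SD is printed), a
  stronger coupling (0.3) between the subscale pairs each disease's network
  was reported to connect tightly, and a weak background (0.05) elsewhere.

Responses are generated by thresholding a latent multivariate normal: family
``f`` answers item ``i`` with risk iff ``z_fi > Phi^{-1}(1 - p_i)``. Items
with prevalence 0 or 1 are legal and produce constant columns (the network
stage drops zero-variance nodes).

The optional sibling scale is drawn (from its own within-subscale block) only
for families sampled as having siblings; other families get missing sibling
responses and score 0 on that subscale, which is why the per-item sibling
prevalence is the published cohort-level sibling mean divided by the
sibling-applicable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import SUBSCALES, ItemCatalog, load_catalog
from .cohort import Cohort

DISEASES = ("ALL", "epilepsy", "asthma")

#: study cohort sizes
COHORT_SIZES = {"ALL": 90, "epilepsy": 42, "asthma": 63}

#: instrument variant administered to each group
DISEASE_VARIANT = {"ALL": "PAT2.0", "epilepsy": "PAT2.0_GEN", "asthma": "PAT2.0_GEN"}

# Published subscale means per disease. Where a mean is not printed
# (ALL structure/social, epilepsy sibling) the value is the residual that makes
# the subscale means sum to the published total (1.44 ALL, 1.0 epilepsy).
# The asthma means are all published and sum to 0.922 (printed total 0.90).
SUBSCALE_MEANS: dict[str, dict[str, float]] = {
    "ALL": {
        "structure_resources": 0.05,
        "social_support": 0.04,
        "child_problems": 0.37,
        "family_problems": 0.19,
        "caregiver_stress": 0.29,
        "family_beliefs": 0.46,
        "sibling_problems": 0.04,
    },
    "epilepsy": {
        "structure_resources": 0.05,
        "social_support": 0.02,
        "child_problems": 0.39,
        "family_problems": 0.17,
        "caregiver_stress": 0.15,
        "family_beliefs": 0.17,
        "sibling_problems": 0.05,
    },
    "asthma": {
        "structure_resources": 0.10,
        "social_support": 0.08,
        "child_problems": 0.34,
        "family_problems": 0.14,
        "caregiver_stress": 0.054,
        "family_beliefs": 0.20,
        "sibling_problems": 0.008,
    },
}

#: published item-level prevalence anchors (catalog labels)
ITEM_ANCHORS: dict[str, dict[str, float]] = {
    "ALL": {"pchangemood": 0.80, "exec worry": 0.58, "saddness-depr": 0.24},
    "epilepsy": {"pchangemood": 0.50, "pdistracted": 0.80},
    "asthma": {"pchangemood": 0.60},
}

# Published subscale SDs (None where the paper prints no SD). Sibling SDs are
# cohort-level, i.e. they include the zeros of families without siblings.
# The asthma sibling SD (0.26 at mean 0.008) exceeds the maximum attainable
# for a [0,1] variable with that mean; the calibrated correlation clamps at
# its upper bound there.
SUBSCALE_SDS: dict[str, dict[str, Optional[float]]] = {
    "ALL": {
        "structure_resources": None,
        "social_support": None,
        "child_problems": 0.19,
        "family_problems": 0.13,
        "caregiver_stress": 0.22,
        "family_beliefs": 0.17,
        "sibling_problems": 0.13,
    },
    "epilepsy": {
        "structure_resources": 0.09,
        "social_support": 0.07,
        "child_problems": 0.20,
        "family_problems": 0.14,
        "caregiver_stress": 0.27,
        "family_beliefs": 0.20,
        "sibling_problems": None,
    },
    "asthma": {
        "structure_resources": 0.16,
        "social_support": 0.18,
        "child_problems": 0.20,
        "family_problems": 0.18,
        "caregiver_stress": 0.16,
        "family_beliefs": 0.23,
        "sibling_problems": 0.26,
    },
}

#: subscale pairs each disease's network connects tightly
STRONG_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALL": (
        ("child_problems", "caregiver_stress"),
        ("family_beliefs", "structure_resources"),
    ),
    "epilepsy": (
        ("child_problems", "structure_resources"),
        ("caregiver_stress", "family_beliefs"),
    ),
    "asthma": (("structure_resources", "social_support"),),
}

RHO_WITHIN = 0.4
RHO_STRONG = 0.3
RHO_BACKGROUND = 0.05
SIBLING_APPLICABLE_RATE = 0.8

_PSD_EPS = 1e-8


def nearest_psd_correlation(matrix: np.ndarray, eps: float = _PSD_EPS) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to a unit diagonal."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= eps:
        return matrix
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def block_correlation(
    items: tuple,
    rho_within: float | Mapping[str, float] = RHO_WITHIN,
    rho_background: float = RHO_BACKGROUND,
    strong_pairs: tuple[tuple[str, str], ...] = (),
    rho_strong: float = RHO_STRONG,
) -> pd.DataFrame:
    """Block-structured latent correlation over a set of catalog items.

    ``rho_within`` is a scalar or a per-subscale map.
    """
    strong = {frozenset(p) for p in strong_pairs}
    n = len(items)
    mat = np.full((n, n), rho_background)
    for i, a in enumerate(items):
        for j, b in enumerate(items):
            if i == j:
                mat[i, j] = 1.0
            elif a.subscale == b.subscale:
                if isinstance(rho_within, Mapping):
                    mat[i, j] = rho_within.get(a.subscale, RHO_WITHIN)
                else:
                    mat[i, j] = rho_within
            elif frozenset((a.subscale, b.subscale)) in strong:
                mat[i, j] = rho_strong
    mat = nearest_psd_correlation(mat)
    ids = [it.item_id for it in items]
    return pd.DataFrame(mat, index=ids, columns=ids)


def binary_covariance(p_i: float, p_j: float, rho: float) -> float:
    """Covariance of two thresholded-normal Bernoulli variables.

    ``P(both 1) = Phi2(-h_i, -h_j; rho)`` with ``h = Phi^{-1}(1 - p)``.
    """
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        return 0.0
    h_i, h_j = stats.norm.ppf(1 - p_i), stats.norm.ppf(1 - p_j)
    p_both = float(
        stats.multivariate_normal.cdf(
            [-h_i, -h_j], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
    )
    return p_both - p_i * p_j


def subscale_score_sd(prevalences, rho: float) -> float:
    """Model-implied SD of a subscale score (mean of correlated Bernoullis
    sharing one within-subscale latent correlation ``rho``)."""
    p = np.asarray(list(prevalences), dtype=float)
    m = len(p)
    var = float(np.sum(p * (1 - p)))
    cache: dict[tuple[float, float], float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            key = (min(p[i], p[j]), max(p[i], p[j]))
            if key not in cache:
                cache[key] = binary_covariance(key[0], key[1], rho)
            var += 2.0 * cache[key]
    return math.sqrt(max(var, 0.0) / m ** 2)


def solve_within_rho(prevalences, target_sd: float) -> float:
    """Latent within-subscale correlation matching a target subscale-score SD.

    Clamped to the PSD-feasible range ``(-1/(m-1), 0.95]``; targets outside
    the attainable SD range return the nearest bound.
    """
    p = [q for q in prevalences]
    m = len(p)
    lo = -1.0 / (m - 1) + 0.02 if m > 1 else 0.0
    hi = 0.95

    def gap(rho: float) -> float:
        return subscale_score_sd(p, rho) - target_sd

    if gap(lo) >= 0.0:
        return lo
    if gap(hi) <= 0.0:
        return hi
    return float(optimize.brentq(gap, lo, hi, xtol=1e-4))


@dataclass
class DiseaseProfile:
    """Generator parameters for one disease cohort.

    ``item_prevalence`` covers every scored item of the catalog (sibling
    prevalences are conditional on the scale being applicable);
    ``latent_correlation`` is defined over the 38 in-network items, and the
    sibling block uses ``sibling_rho`` within-scale.
    """

    disease: str
    n_default: int
    item_prevalence: dict[str, float]
    latent_correlation: pd.DataFrame
    catalog: ItemCatalog
    sibling_applicable_rate: float = SIBLING_APPLICABLE_RATE
    sibling_rho: float = RHO_WITHIN
    _chol: Optional[np.ndarray] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        for item_id, p in self.item_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of item {item_id!r} is {p}, outside [0, 1]")
        mat = self.latent_correlation.to_numpy()
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ValueError("latent correlation must be symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
            raise ValueError("latent correlation must have a unit diagonal")
        vals = np.linalg.eigvalsh(mat)
        if vals.min() < -1e-10:
            raise ValueError(
                f"latent correlation is not positive semi-definite "
                f"(min eigenvalue {vals.min():.3e}); repair it first"
            )

    def expected_subscale_means(self) -> dict[str, float]:
        """Analytic expected subscale scores (mean item prevalence; the
        sibling scale is attenuated by the applicable rate)."""
        out = {}
        for sub in self.catalog.subscales_present():
            ids = [it.item_id for it in self.catalog.subscale_items(sub)]
            m = float(np.mean([self.item_prevalence[i] for i in ids]))
            if sub == "sibling_problems":
                m *= self.sibling_applicable_rate
            out[sub] = m
        return out

    def expected_total_mean(self) -> float:
        return float(sum(self.expected_subscale_means().values()))


def calibrate_profile(
    disease: str,
    overrides: Optional[Mapping[str, float]] = None,
    catalog: Optional[ItemCatalog] = None,
) -> DiseaseProfile:
    """Build the default, publication-calibrated profile for one disease.

    Every item on a subscale starts at the subscale's published mean; the
    published item anchors are then imposed and the remaining items on that
    subscale renormalised so the subscale mean (hence the expected total) is
    unchanged. ``overrides`` (item id or label → probability) are applied
    last, verbatim.
    """
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}; expected one of {DISEASES}")
    if catalog is None:
        catalog = load_catalog(DISEASE_VARIANT[disease])

    means = SUBSCALE_MEANS[disease]
    anchors_by_id: dict[str, float] = {}
    for label, p in ITEM_ANCHORS[disease].items():
        item = catalog.get(label)
        anchors_by_id[item.item_id] = p

    prevalence: dict[str, float] = {}
    for sub in catalog.subscales_present():
        items = catalog.subscale_items(sub)
        mu = means[sub]
        if sub == "sibling_problems":
            mu = mu / SIBLING_APPLICABLE_RATE
        sub_anchors = {it.item_id: anchors_by_id[it.item_id]
                       for it in items if it.item_id in anchors_by_id}
        free = [it for it in items if it.item_id not in sub_anchors]
        if sub_anchors:
            residual = (len(items) * mu - sum(sub_anchors.values())) / len(free)
            if not 0.0 <= residual <= 1.0:
                raise ValueError(
                    f"anchors on {sub} leave an infeasible residual prevalence {residual:.3f}"
                )
        else:
            residual = mu
        for it in items:
            prevalence[it.item_id] = sub_anchors.get(it.item_id, residual)

    if overrides:
        for key, p in overrides.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"override for {key!r} is {p}, outside [0, 1]")
            prevalence[catalog.get(key).item_id] = float(p)

    # within-subscale latent correlations: solved against the published
    # subscale SD where one is printed, the generic default otherwise
    rho_target: dict[str, float] = {}
    sibling_rho = RHO_WITHIN
    for sub in catalog.subscales_present():
        target_sd = SUBSCALE_SDS[disease][sub]
        if target_sd is None:
            if sub != "sibling_problems":
                rho_target[sub] = RHO_WITHIN
            continue
        ps = [prevalence[it.item_id] for it in catalog.subscale_items(sub)]
        if sub == "sibling_problems":
            # printed sibling SDs are cohort-level: families without siblings
            # score 0, so back out the conditional variance through the
            # applicable rate r: Var_cond = SD^2 / r - mean^2 (1 - r)
            r = SIBLING_APPLICABLE_RATE
            p_bar = float(np.mean(ps))
            var_cond = target_sd ** 2 / r - p_bar ** 2 * (1.0 - r)
            target_cond_sd = math.sqrt(max(var_cond, 0.0))
            sibling_rho = solve_within_rho(ps, target_cond_sd)
        else:
            rho_target[sub] = solve_within_rho(ps, target_sd)

    # The PSD repair of the assembled block matrix can pull strongly negative
    # within-block values back toward zero; a short fixed-point iteration
    # re-adjusts the inputs so the *repaired* within-block correlations land
    # on their calibrated targets (up to global PSD feasibility).
    rho_within = dict(rho_target)
    items = catalog.network_items
    for _ in range(10):
        corr = block_correlation(
            items, rho_within=rho_within, strong_pairs=STRONG_PAIRS[disease]
        )
        max_dev = 0.0
        for sub, rho_t in rho_target.items():
            ids = [it.item_id for it in catalog.subscale_items(sub) if it.in_network]
            m = len(ids)
            if m < 2:
                continue
            blk = corr.loc[ids, ids].to_numpy()
            realized = (blk.sum() - m) / (m * (m - 1))
            dev = rho_t - realized
            max_dev = max(max_dev, abs(dev))
            lo = -1.0 / (m - 1) - 0.1  # may overshoot; repair restores PSD
            rho_within[sub] = min(max(rho_within[sub] + dev, lo), 0.95)
        if max_dev < 1e-3:
            break
    return DiseaseProfile(
        disease=disease,
        n_default=COHORT_SIZES[disease],
        item_prevalence=prevalence,
        latent_correlation=corr,
        catalog=catalog,
        sibling_rho=sibling_rho,
    )


def generate_cohort(
    profile: DiseaseProfile,
    n: Optional[int] = None,
    seed: int = 0,
    timepoint: str = "T0",
) -> Cohort:
    """Draw a cohort of correlated dichotomous responses.

    One seeded generator drives the whole cohort; draws are consumed family by
    family (sibling-applicability first, then the 38-dimensional network
    block, the non-network items, and — when applicable — the sibling block),
    so the output is byte-for-byte reproducible for identical
    ``(profile, n, seed)``.
    """
    if n is None:
        n = profile.n_default
    if n < 1:
        raise ValueError("n must be >= 1")
    catalog = profile.catalog
    rng = np.random.default_rng(seed)

    net_ids = [it.item_id for it in catalog.network_items]
    extra_ids = [
        it.item_id for it in catalog.items
        if not it.in_network and it.subscale != "sibling_problems"
    ]
    sib_ids = [it.item_id for it in catalog.subscale_items("sibling_problems")]

    corr = profile.latent_correlation.loc[net_ids, net_ids].to_numpy()
    try:
        chol = np.linalg.cholesky(corr + _PSD_EPS * np.eye(len(net_ids)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValueError("latent correlation is not positive semi-definite") from exc

    k_sib = len(sib_ids)
    sib_corr = np.full((k_sib, k_sib), profile.sibling_rho)
    np.fill_diagonal(sib_corr, 1.0)
    chol_sib = np.linalg.cholesky(sib_corr + _PSD_EPS * np.eye(k_sib)) if k_sib else None

    # thresholds: response = 1 iff latent > Phi^{-1}(1 - p)
    thr_net = stats.norm.ppf(1.0 - np.array([profile.item_prevalence[i] for i in net_ids]))
    thr_sib = stats.norm.ppf(1.0 - np.array([profile.item_prevalence[i] for i in sib_ids]))
    p_extra = np.array([profile.item_prevalence[i] for i in extra_ids])
    thr_extra = stats.norm.ppf(1.0 - p_extra)

    rows = []
    width = len(str(n))
    for f in range(n):
        sib_applicable = bool(rng.uniform() < profile.sibling_applicable_rate)
        z_net = chol @ rng.standard_normal(len(net_ids))
        z_extra = rng.standard_normal(len(extra_ids))
        row: dict = {
            "family_id": f"{profile.disease}-{seed}-{f + 1:0{width}d}",
            "disease": profile.disease,
            "timepoint": timepoint,
            "sibling_applicable": sib_applicable,
        }
        for item_id, z, t in zip(net_ids, z_net, thr_net):
            row[item_id] = float(z > t)
        for item_id, z, t in zip(extra_ids, z_extra, thr_extra):
            row[item_id] = float(z > t)
        if sib_applicable and k_sib:
            z_sib = chol_sib @ rng.standard_normal(k_sib)
            for item_id, z, t in zip(sib_ids, z_sib, thr_sib):
                row[item_id] = float(z > t)
        else:
            for item_id in sib_ids:
                row[item_id] = float("nan")
        rows.append(row)

    frame = pd.DataFrame(
        rows, columns=["family_id", "disease", "timepoint", "sibling_applicable"]
        + list(catalog.item_ids)
    )
    return Cohort(frame=frame, catalog=catalog)
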