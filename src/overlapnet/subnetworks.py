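"""Subnetwork analytics on a trained model.

Per-unit reconstruction importance (decode one unit with all others clamped
to their training means), signed region-relevance matrices read off the
decoder, optimal-assignment stability correlations between solutions, and
cluster-level aggregation of absolute relevances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .atlas import CLUSTERS, SocialBrainAtlas, cluster_membership_matrix
from .autoencoders import AutoencoderModel, explained_variance_score
from .errors import ConfigMismatchError, ModelStateError, ShapeMismatchError


@dataclass
class SubnetworkRelevance:
    """K x R signed region relevances for each latent unit."""

    matrix: np.ndarray
    region_names: list[str] | None = None
    scale: str = "raw_decoder"  # or "zscored"
    sign_convention: str = "max_abs_positive"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ShapeMismatchError("relevance matrix must be 2-D (units x regions)")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]

    def zscored(self) -> "SubnetworkRelevance":
        m = self.matrix
        z = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, ddof=0, keepdims=True)
        return SubnetworkRelevance(z, self.region_names, scale="zscored",
                                   sign_convention=self.sign_convention)

    def to_frame(self) -> pd.DataFrame:
        cols = self.region_names or [f"region_{j:02d}" for j in range(self.n_regions)]
        return pd.DataFrame(self.matrix, columns=cols,
                            index=[f"subnetwork_{k + 1}" for k in range(self.n_units)])


@dataclass
class SubnetworkRanking:
    """Per-unit explained-variance scores with a dominance ordering."""

    scores: np.ndarray  # per unit, in unit order
    order: np.ndarray  # unit indices sorted by descending score
    elbow: int  # 1-based count of dominant units (before the largest drop)
    baseline_score: float  # all units clamped to their training means

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": self.order,
            "rank": np.arange(1, len(self.order) + 1),
            "score": self.scores[self.order],
        })


@dataclass
class StabilityReport:
    """Matched absolute Pearson correlations between two relevance sets."""

    mean_abs_rho: float
    sd_abs_rho: float
    matching: np.ndarray  # matching[i] = row of B matched to row i of A
    matched_rho: np.ndarray  # signed rho per matched pair


def _apply_sign_convention(matrix: np.ndarray) -> np.ndarray:
    out = matrix.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def relevance_matrix(
    model: AutoencoderModel,
    region_names: list[str] | None = None,
    side: str = "decoder",
) -> SubnetworkRelevance:
    """Signed relevance of each region to each latent unit.

    Default reads the decoder (unit -> region weights); for deep decoders the
    weight matrices are composed, i.e. the linearized latent-to-region map.
    ``side="encoder"`` composes the encoder weights instead.
    """
    if side == "decoder":
        mats = model.weights[model.bottleneck_layer + 1:]
        lin = mats[0]
        for w in mats[1:]:
            lin = lin @ w
        rel = lin  # (K, R)
    elif side == "encoder":
        mats = model.weights[:model.bottleneck_layer + 1]
        lin = mats[0]
        for w in mats[1:]:
            lin = lin @ w
        rel = lin.T  # (K, R)
    else:
        raise ValueError(f"unknown side {side!r}")
    return SubnetworkRelevance(_apply_sign_convention(rel), region_names)


def per_subnetwork_score(model: AutoencoderModel, x: np.ndarray) -> SubnetworkRanking:
    """Score each unit by decoding it alone, others clamped at training means."""
    if model.bottleneck_means is None:
        raise ModelStateError("model has no stored training-set bottleneck means")
    x = np.asarray(x, dtype=float)
    h = model.encode(x)
    k = h.shape[1]
    clamped = np.tile(model.bottleneck_means, (x.shape[0], 1))
    baseline = explained_variance_score(x, model.decode(clamped))
    scores = np.empty(k)
    for unit in range(k):
        masked = clamped.copy()
        masked[:, unit] = h[:, unit]
        scores[unit] = explained_variance_score(x, model.decode(masked))
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    drops = -np.diff(sorted_scores)
    elbow = int(np.argmax(drops)) + 1 if k > 1 else 1
    return SubnetworkRanking(scores=scores, order=order, elbow=elbow,
                             baseline_score=float(baseline))


def _abs_corr_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(|rho|, rho) matrices between rows of a and rows of b."""
    ka, kb = a.shape[0], b.shape[0]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ac @ bc.T) / np.outer(an, bn)
    rho = np.nan_to_num(rho, nan=0.0)
    return np.abs(rho), rho


def match_and_correlate(a: SubnetworkRelevance, b: SubnetworkRelevance) -> StabilityReport:
    """Optimal bijective matching maximizing total |Pearson rho| between rows."""
    if a.matrix.shape != b.matrix.shape:
        raise ShapeMismatchError(
            f"relevance shapes differ: {a.matrix.shape} vs {b.matrix.shape}"
        )
    abs_rho, rho = _abs_corr_matrix(a.matrix, b.matrix)
    rows, cols = linear_sum_assignment(-abs_rho)
    matched_abs = abs_rho[rows, cols]
    return StabilityReport(
        mean_abs_rho=float(matched_abs.mean()),
        sd_abs_rho=float(matched_abs.std(ddof=0)),
        matching=cols.copy(),
        matched_rho=rho[rows, cols].copy(),
    )


def permutation_null_stability(
    a: SubnetworkRelevance,
    b: SubnetworkRelevance,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of mean matched |rho| under region shuffling of B."""
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(b.n_regions)
        shuffled = SubnetworkRelevance(b.matrix[:, perm], b.region_names)
        nulls[i] = match_and_correlate(a, shuffled).mean_abs_rho
    return nulls


def cluster_relevance(rel: SubnetworkRelevance, atlas: SocialBrainAtlas) -> pd.DataFrame:
    """(4 clusters x K units) mean absolute relevance per functional cluster."""
    if rel.n_regions != len(atlas):
        raise ShapeMismatchError(
            f"relevance has {rel.n_regions} regions, atlas has {len(atlas)}"
        )
    membership = cluster_membership_matrix(atlas).to_numpy()  # (4, R)
    sizes = membership.sum(axis=1, keepdims=True)
    agg = (membership @ np.abs(rel.matrix).T) / sizes  # (4, K)
    return pd.DataFrame(agg, index=list(CLUSTERS),
                        columns=[f"subnetwork_{k + 1}" for k in range(rel.n_units)])


def compare_runs(
    model_a: AutoencoderModel,
    model_b: AutoencoderModel,
    x_a: np.ndarray | None = None,
    x_b: np.ndarray | None = None,
    region_names: list[str] | None = None,
) -> tuple[StabilityReport, float]:
    """Stability between two independently trained runs of one architecture.

    Returns the matched-relevance stability report and the difference of
    held-out scores (a - b) when evaluation matrices are supplied (else 0).
    """
    sa, sb = model_a.spec, model_b.spec
    if (sa.latent_layers, sa.activation, sa.tied_weights) != (
            sb.latent_layers, sb.activation, sb.tied_weights):
        raise ConfigMismatchError(
            f"architectures differ: {sa.name}/{sa.latent_layers} vs {sb.name}/{sb.latent_layers}"
        )
    rel_a = relevance_matrix(model_a, region_names)
    rel_b = relevance_matrix(model_b, region_names)
    report = match_and_correlate(rel_a, rel_b)
    delta = 0.0
    if x_a is not None and x_b is not None:
        delta = model_a.score(np.asarray(x_a)) - model_b.score(np.asarray(x_b))
    return report, delta
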