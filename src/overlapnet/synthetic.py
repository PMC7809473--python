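"""Synthetic populations with planted, partially overlapping latent subnetworks.

Volumes follow a linear factor model X = Z W' + noise where loading supports
overlap on designated hub regions (each hub loads on >= 3 factors). Binary
social-trait labels are generated from the latents through a logistic link,
with sex and age covariates. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import SocialBrainAtlas
from .errors import InfeasibleSupportError, OutOfBoundsError, SpecError
from .roi import GreyMatterImage, VolumeMatrix


def default_factor_variances(k: int, base: float = 4.0, ratio: float = 0.8) -> np.ndarray:
    """Geometric variance profile (descending) giving a clear dominance order."""
    return base * ratio ** np.arange(k)


@dataclass
class SyntheticSpec:
    """Parameters of the planted factor model and trait generator.

    ``overlap`` is one of:
      - ``"hubs"``: ``n_hubs`` regions are each planted into >= 3 factor
        supports (mimicking hub regions recurring across leading subnetworks);
      - ``"disjoint"``: contiguous non-overlapping supports;
      - a mapping ``{region_index: [factor indices]}`` for explicit hubs.
    """

    n_participants: int = 1000
    n_regions: int = 36
    n_factors: int = 15
    support_size: int = 6
    overlap: str | Mapping[int, Sequence[int]] = "hubs"
    n_hubs: int = 3
    factor_variances: np.ndarray | None = None
    noise_sd: float = 0.5
    latent_dist: str = "gaussian"  # or "t" (df 5, heavy-tailed stress test)
    orthonormal: bool = False
    n_traits: int = 6
    trait_effect: float = 1.0
    beta: np.ndarray | None = None  # (n_traits, n_factors); overrides trait_effect
    gamma: np.ndarray | None = None  # per-trait sex effect, default zeros
    age_range: tuple[float, float] = (45.0, 80.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_factors > self.n_regions:
            raise SpecError("n_factors must not exceed n_regions")
        if self.support_size < 1 or self.support_size > self.n_regions:
            raise SpecError("support_size out of range")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be nonnegative")
        if self.latent_dist not in ("gaussian", "t"):
            raise SpecError(f"unknown latent_dist {self.latent_dist!r}")
        if self.factor_variances is None:
            self.factor_variances = default_factor_variances(self.n_factors)
        self.factor_variances = np.asarray(self.factor_variances, dtype=float)
        if self.factor_variances.shape != (self.n_factors,):
            raise SpecError("factor_variances must have length n_factors")
        if np.any(self.factor_variances <= 0):
            raise SpecError("factor variances must be positive")
        if np.any(np.diff(self.factor_variances) > 1e-12):
            raise SpecError("factor variances must be descending")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.n_traits, self.n_factors):
                raise SpecError("beta must be (n_traits, n_factors)")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape != (self.n_traits,):
                raise SpecError("gamma must have length n_traits")

    def trait_betas(self) -> np.ndarray:
        """Effect vectors; default: trait t loads only on factor t (mod K)."""
        if self.beta is not None:
            return self.beta
        beta = np.zeros((self.n_traits, self.n_factors))
        for t in range(self.n_traits):
            beta[t, t % self.n_factors] = self.trait_effect
        return beta

    def trait_gammas(self) -> np.ndarray:
        return self.gamma if self.gamma is not None else np.zeros(self.n_traits)


@dataclass
class SyntheticDataset:
    """Planted ground truth plus the observable volume matrix."""

    volumes: VolumeMatrix
    latents: np.ndarray
    loadings: np.ndarray  # (n_regions, n_factors), as actually used
    spec: SyntheticSpec
    covariates: pd.DataFrame | None = None

    @property
    def trait_columns(self) -> list[str]:
        if self.covariates is None:
            return []
        return [c for c in self.covariates.columns if c.startswith("trait_")]


def _plan_supports(spec: SyntheticSpec, rng: np.random.Generator) -> list[np.ndarray]:
    r, k, s = spec.n_regions, spec.n_factors, spec.support_size
    if spec.overlap == "disjoint":
        if k * s < r:
            raise InfeasibleSupportError(
                f"disjoint supports of size {s} x {k} factors cannot cover {r} regions"
            )
        supports = []
        for j in range(k):
            block = np.arange(j * s, min((j + 1) * s, r))
            if block.size == 0:
                raise InfeasibleSupportError("more factors than disjoint blocks")
            supports.append(block)
        return supports

    # coverage first: round-robin every region into one factor
    supports = [set(np.arange(j, r, k)) for j in range(k)]
    if isinstance(spec.overlap, Mapping):
        hub_plan = {int(reg): list(facs) for reg, facs in spec.overlap.items()}
    elif spec.overlap == "hubs":
        hub_plan = {}
        hubs = rng.choice(r, size=min(spec.n_hubs, r), replace=False)
        for h in hubs:
            n_mem = 3 if k >= 3 else k
            hub_plan[int(h)] = rng.choice(k, size=n_mem, replace=False).tolist()
    else:
        raise SpecError(f"unknown overlap plan {spec.overlap!r}")
    for reg, facs in hub_plan.items():
        if reg >= r or any(f >= k for f in facs):
            raise InfeasibleSupportError(f"hub plan {reg}:{facs} outside atlas/factor range")
        for f in facs:
            supports[f].add(reg)
    # pad to support_size with random extras
    for j in range(k):
        deficit = s - len(supports[j])
        if deficit > 0:
            pool = np.array(sorted(set(range(r)) - supports[j]))
            supports[j].update(rng.choice(pool, size=deficit, replace=False).tolist())
    return [np.array(sorted(sup)) for sup in supports]


def generate_loadings(spec: SyntheticSpec) -> np.ndarray:
    """Sparse (R, K) loading matrix: planned supports, unit-norm columns."""
    rng = np.random.default_rng([spec.seed, 0])
    supports = _plan_supports(spec, rng)
    covered = set()
    for sup in supports:
        covered.update(sup.tolist())
    if covered != set(range(spec.n_regions)):
        raise InfeasibleSupportError(
            f"supports leave regions {sorted(set(range(spec.n_regions)) - covered)} uncovered"
        )
    w = np.zeros((spec.n_regions, spec.n_factors))
    for j, sup in enumerate(supports):
        vals = rng.normal(size=sup.size)
        # keep entries bounded away from zero so supports are unambiguous
        vals = np.sign(vals) * (0.3 + np.abs(vals))
        w[sup, j] = vals
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    return w


def simulate_volumes(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw X = Z W' + eps with planted loadings; bit-reproducible per seed."""
    w = generate_loadings(spec)
    if spec.orthonormal:
        q, rmat = np.linalg.qr(w)
        w = q * np.sign(np.diag(rmat))  # fix QR sign ambiguity deterministically
    rng = np.random.default_rng([spec.seed, 1])
    n, k = spec.n_participants, spec.n_factors
    if spec.latent_dist == "gaussian":
        z = rng.normal(size=(n, k))
    else:
        df = 5.0
        z = rng.standard_t(df, size=(n, k)) / np.sqrt(df / (df - 2.0))
    z *= np.sqrt(spec.factor_variances)
    x = z @ w.T
    if spec.noise_sd > 0:
        x = x + rng.normal(scale=spec.noise_sd, size=x.shape)
    ids = [f"sub-{i:05d}" for i in range(n)]
    names = [f"region_{j:02d}" for j in range(spec.n_regions)]
    vm = VolumeMatrix(x, ids, names, standardized=False)
    return SyntheticDataset(volumes=vm, latents=z, loadings=w, spec=spec)


def simulate_traits(ds: SyntheticDataset, spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Fill sex/age covariates and binary traits via a logistic link on Z."""
    spec = spec or ds.spec
    rng = np.random.default_rng([spec.seed, 2])
    n = ds.latents.shape[0]
    sex = rng.integers(0, 2, size=n)  # 1 = female
    age = rng.uniform(*spec.age_range, size=n)
    beta = spec.trait_betas()
    gamma = spec.trait_gammas()
    cov = pd.DataFrame({"participant_id": ds.volumes.participant_ids,
                        "sex": sex, "age": age}).set_index("participant_id")
    logits = ds.latents @ beta.T + sex[:, None] * gamma[None, :]
    probs = 1.0 / (1.0 + np.exp(-logits))
    draws = rng.uniform(size=probs.shape)
    for t in range(spec.n_traits):
        cov[f"trait_{t}"] = (draws[:, t] < probs[:, t]).astype(int)
    ds.covariates = cov
    return ds


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Volumes + covariates in one call."""
    return simulate_traits(simulate_volumes(spec), spec)


def centered_affine(shape: Sequence[int]) -> np.ndarray:
    """1 mm isotropic affine placing mm (0,0,0) at the grid center."""
    aff = np.eye(4)
    aff[:3, 3] = -(np.asarray(shape) // 2)
    return aff


def make_phantom_images(
    n: int,
    shape: Sequence[int],
    atlas: SocialBrainAtlas,
    signal_plan: Mapping | None = None,
    affine: np.ndarray | None = None,
) -> list[GreyMatterImage]:
    """Images with known signals at region centers (closed-form expectations).

    ``signal_plan`` kinds:
      - ``{"kind": "constant", "value": c}`` — whole image equals ``c``
        (scaled by participant index + 1 if ``per_participant_scale``);
      - ``{"kind": "region_cubes", "values": [c_r...], "cube_mm": 7}`` —
        constant ``c_r`` painted in a cube around each region center;
      - ``{"kind": "points", "value": v}`` — single hot voxel per center.
    """
    plan = dict(signal_plan or {"kind": "constant", "value": 1.0})
    shape = tuple(int(s) for s in shape)
    aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    inv = np.linalg.inv(aff)
    centers = []
    for region in atlas.regions:
        hom = np.append(np.array(region.mni_xyz, dtype=float), 1.0)
        vox = np.rint((inv @ hom)[:3]).astype(int)
        if np.any(vox < 0) or np.any(vox >= np.array(shape)):
            raise OutOfBoundsError(
                f"region {region.name!r} maps to voxel {vox.tolist()} outside {shape}"
            )
        centers.append(vox)

    images = []
    for i in range(n):
        scale = float(i + 1) if plan.get("per_participant_scale") else 1.0
        data = np.zeros(shape)
        kind = plan["kind"]
        if kind == "constant":
            data[:] = plan["value"] * scale
        elif kind == "region_cubes":
            values = plan["values"]
            half = int(plan.get("cube_mm", 7)) // 2
            for c, v in zip(centers, values):
                sl = tuple(slice(max(c[d] - half, 0), c[d] + half + 1) for d in range(3))
                data[sl] = v * scale
        elif kind == "points":
            for c in centers:
                data[tuple(c)] = plan["value"] * scale
        else:
            raise SpecError(f"unknown phantom signal kind {kind!r}")
        images.append(GreyMatterImage(data, aff.copy(), participant_id=f"sub-{i:05d}"))
    return images
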