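"""Synthetic multiview data with known ground truth.

The generative model is a Gaussian linear factor model: latent factors
Z ~ N(0, I) drive each view through a loading matrix, X_v = Z B_v + E_v,
with factors visible either globally or only inside a declared view group —
this manufactures the group structure among datasets (members of a group
correlate strongly, across groups weakly) that hierarchical merging is
designed to exploit.  Phenotypes are linear in the factors with Gaussian
noise, so the attainable R^2 has the closed form |beta|^2/(|beta|^2 +
sigma^2) and two 1-feature views sharing one factor have population
canonical correlation b^2/(b^2 + sigma^2); both serve as exact oracles.

Loading styles
--------------
``modular``
    Each view's features are partitioned into one block per visible factor,
    with constant loading inside the block — the blocks double as the ground
    truth for network-module generation (so Laplacian smoothing should help
    by construction).
``orthonormal``
    Visible factors map to features through an orthonormal matrix.  A group
    whose rank reaches the smaller member view's dimension then yields a
    full-rank, well-conditioned cross-covariance — the regime in which the
    minimum-condition-number rule reliably picks the strongly shared pair.
``dense``
    IID Gaussian loadings scaled by 1/sqrt(r_visible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InteractionNetwork, OmicsMatrix, RunConfig

__all__ = [
    "SyntheticTruth",
    "gen_multiview",
    "gen_network",
    "gen_phenotype",
    "scenario",
    "SCENARIOS",
]


@dataclass
class SyntheticTruth:
    """Generative parameters of a synthetic scenario (the testing oracle)."""

    Z: np.ndarray  # n x r latent factors
    loadings: list[np.ndarray]  # r x d_v per view
    visible: list[list[int]]  # factor indices visible to each view
    module_map: list[dict[int, list[int]]]  # per view: factor -> feature cols
    noise_sd: float
    loading_scale: float
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    # phenotype fields, populated by gen_phenotype
    beta: np.ndarray | None = None
    pheno_noise_sd: float | None = None

    @property
    def n_factors(self) -> int:
        return self.Z.shape[1]

    @property
    def r2_ceiling(self) -> float:
        """Attainable R^2 of the generated phenotype: var(Z beta) over
        var(Z beta) + noise variance (factors are iid standard normal)."""
        if self.beta is None:
            raise ValueError("generate a phenotype first")
        signal = float(self.beta @ self.beta)
        return signal / (signal + self.pheno_noise_sd**2)

    def to_json(self, path) -> None:
        payload = {
            "Z": self.Z.tolist(),
            "loadings": [B.tolist() for B in self.loadings],
            "visible": self.visible,
            "module_map": [
                {str(k): v for k, v in mm.items()} for mm in self.module_map
            ],
            "noise_sd": self.noise_sd,
            "loading_scale": self.loading_scale,
            "seed": self.seed,
            "sample_ids": self.sample_ids,
            "beta": None if self.beta is None else self.beta.tolist(),
            "pheno_noise_sd": self.pheno_noise_sd,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            Z=np.array(d["Z"], dtype=float),
            loadings=[np.array(B, dtype=float) for B in d["loadings"]],
            visible=[list(v) for v in d["visible"]],
            module_map=[
                {int(k): list(v) for k, v in mm.items()} for mm in d["module_map"]
            ],
            noise_sd=d["noise_sd"],
            loading_scale=d["loading_scale"],
            seed=d["seed"],
            sample_ids=list(d["sample_ids"]),
            beta=None if d["beta"] is None else np.array(d["beta"], dtype=float),
            pheno_noise_sd=d["pheno_noise_sd"],
        )


def _visibility(n_views: int, r_shared: int, r_group: dict | None):
    """Factor layout: global factors first, then each group's block."""
    groups = []
    if r_group:
        for key in sorted(r_group, key=lambda t: tuple(t)):
            members = tuple(sorted(key)) if not isinstance(key, int) else (key,)
            if any(not 0 <= v < n_views for v in members):
                raise ValueError(f"group {key} names an unknown view")
            if r_group[key] < 1:
                raise ValueError(f"group {key} must contribute >= 1 factor")
            groups.append((members, int(r_group[key])))
    r_total = r_shared + sum(r for _, r in groups)
    visible = [list(range(r_shared)) for _ in range(n_views)]
    offset = r_shared
    for members, r in groups:
        for v in members:
            visible[v].extend(range(offset, offset + r))
        offset += r
    return r_total, visible


def gen_multiview(
    n: int,
    dims: list[int],
    r_shared: int = 1,
    r_group: dict | None = None,
    loading_scale: float = 1.0,
    noise_sd: float = 0.5,
    loading: str = "modular",
    seed: int = 0,
    view_names: list[str] | None = None,
    factor_scale=None,
) -> tuple[list[OmicsMatrix], SyntheticTruth]:
    """Draw sample-aligned views X_v = Z_visible(v) B_v + noise.

    ``r_group`` maps a tuple of view indices to the number of latent factors
    shared exclusively by those views; ``r_shared`` factors are global.
    ``factor_scale`` optionally rescales individual factors' loadings (length
    r_total, multiplied on top of ``loading_scale``), letting some factors
    drive the views more strongly than others.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if any(d < 1 for d in dims):
        raise ValueError("all dims must be >= 1")
    if loading not in {"modular", "orthonormal", "dense"}:
        raise ValueError(f"unknown loading style {loading!r}")
    rng = np.random.default_rng(seed)
    n_views = len(dims)
    r_total, visible = _visibility(n_views, r_shared, r_group)
    if r_total < 1:
        raise ValueError("the model needs at least one factor")
    if factor_scale is None:
        factor_scale = np.ones(r_total)
    else:
        factor_scale = np.asarray(factor_scale, dtype=float)
        if factor_scale.shape != (r_total,):
            raise ValueError(f"factor_scale must have length {r_total}")
    Z = rng.standard_normal((n, r_total))
    sample_ids = [f"acc{i:04d}" for i in range(n)]
    view_names = view_names or [f"view{v}" for v in range(n_views)]

    views: list[OmicsMatrix] = []
    loadings: list[np.ndarray] = []
    module_map: list[dict[int, list[int]]] = []
    for v, d in enumerate(dims):
        vis = visible[v]
        B = np.zeros((r_total, d))
        modules: dict[int, list[int]] = {}
        if vis:
            if loading == "modular":
                blocks = np.array_split(np.arange(d), len(vis))
                for f, cols in zip(vis, blocks):
                    B[f, cols] = loading_scale * factor_scale[f]
                    modules[f] = [int(c) for c in cols]
            elif loading == "orthonormal":
                if len(vis) > d:
                    raise ValueError(
                        f"view {v}: orthonormal loading needs <= {d} visible "
                        f"factors, got {len(vis)}"
                    )
                Q, _ = np.linalg.qr(rng.standard_normal((d, len(vis))))
                B[vis, :] = loading_scale * factor_scale[vis, None] * Q.T
            else:  # dense
                B[vis, :] = (
                    loading_scale
                    * factor_scale[vis, None]
                    * rng.standard_normal((len(vis), d))
                    / np.sqrt(len(vis))
                )
        X = Z @ B + noise_sd * rng.standard_normal((n, d))
        feature_ids = [f"{view_names[v]}:g{j:04d}" for j in range(d)]
        views.append(
            OmicsMatrix(sample_ids=sample_ids, feature_ids=feature_ids, values=X, name=view_names[v])
        )
        loadings.append(B)
        module_map.append(modules)

    truth = SyntheticTruth(
        Z=Z,
        loadings=loadings,
        visible=visible,
        module_map=module_map,
        noise_sd=noise_sd,
        loading_scale=loading_scale,
        seed=seed,
        sample_ids=sample_ids,
    )
    return views, truth


def gen_network(
    feature_ids: list[str],
    module_map: dict[int, list[int]],
    p_within: float,
    p_between: float,
    seed: int = 0,
) -> InteractionNetwork:
    """Stochastic block graph whose blocks are the loading modules.

    Two features in the same module connect with probability ``p_within``,
    otherwise ``p_between``; overlapping modules are allowed (the higher
    probability wins for pairs sharing a module).
    """
    if not p_within > p_between >= 0:
        raise ValueError("need p_within > p_between >= 0")
    rng = np.random.default_rng(seed)
    member: dict[int, set[int]] = {}
    for f, cols in module_map.items():
        for c in cols:
            member.setdefault(c, set()).add(f)
    net = InteractionNetwork()
    d = len(feature_ids)
    for i in range(d):
        mi = member.get(i, set())
        for j in range(i + 1, d):
            p = p_within if mi & member.get(j, set()) else p_between
            if p > 0 and rng.random() < p:
                net.add_edge(feature_ids[i], feature_ids[j], 1.0)
    return net


def gen_phenotype(
    truth: SyntheticTruth,
    beta,
    noise_sd: float,
    seed: int = 0,
) -> pd.Series:
    """y = Z beta + eps, keyed by sample ID; records the analytic ceiling."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (truth.n_factors,):
        raise ValueError(
            f"beta must have length {truth.n_factors}, got {beta.shape}"
        )
    rng = np.random.default_rng(seed)
    y = truth.Z @ beta + noise_sd * rng.standard_normal(truth.Z.shape[0])
    truth.beta = beta
    truth.pheno_noise_sd = float(noise_sd)
    return pd.Series(y, index=truth.sample_ids, name="phenotype")


# ---------------------------------------------------------------------------
# canned scenarios (fixed study conditions; seed only moves the noise)


def _scenario_two_view_1d(seed: int) -> dict:
    views, truth = gen_multiview(
        n=2000,
        dims=[1, 1],
        r_shared=1,
        loading_scale=1.0,
        noise_sd=0.5,
        loading="modular",
        seed=seed,
    )
    # population canonical correlation b^2 / (b^2 + sigma^2) = 1 / 1.25
    return {"views": views, "truth": truth, "rho_population": 1.0 / 1.25}


def _scenario_grouped3(seed: int) -> dict:
    """Views 0 and 1 share a full-rank latent space; view 2 is independent."""
    views, truth = gen_multiview(
        n=150,
        dims=[15, 15, 15],
        r_shared=0,
        r_group={(0, 1): 15, (2,): 15},
        loading_scale=1.0,
        noise_sd=0.5,
        loading="orthonormal",
        seed=seed,
    )
    return {"views": views, "truth": truth, "planted_pair": (0, 1)}


def _scenario_fourview(seed: int) -> dict:
    """Three wide 'genomic' views plus one narrow 'geoclimate' view.

    Four phenotype-driving factors are visible in every view (full-strength
    loadings), so each view is a noisy partial witness of the same signal:
    a single view recovers ~83% of each factor's variance while the four
    views jointly recover ~95%, which is what integration buys.  On top of
    that, group A = (mutation, climate) and group B = (expression,
    methylation) each share a weaker full-rank latent space of their own,
    which makes the within-group cross-covariances well-conditioned — the
    minimum-kappa rule therefore pairs the narrow climate view with mutation
    first, mirroring the application's merge order.  Phenotype noise is set
    for an analytic R^2 ceiling of 0.5.
    """
    n = 300
    n_pheno = 4
    r_a, r_b = 8, 36  # group ranks; fill the smaller member view's dimension
    factor_scale = np.concatenate([np.ones(n_pheno), 0.7 * np.ones(r_a + r_b)])
    views, truth = gen_multiview(
        n=n,
        dims=[40, 40, 40, 12],
        r_shared=n_pheno,
        r_group={(0, 3): r_a, (1, 2): r_b},
        loading_scale=1.0,
        noise_sd=0.45,
        loading="orthonormal",
        seed=seed,
        view_names=["mutation", "expression", "methylation", "climate"],
        factor_scale=factor_scale,
    )
    beta = np.zeros(truth.n_factors)
    beta[:n_pheno] = 1.0
    pheno_noise = 2.0  # ceiling = 4 / (4 + 4) = 0.5
    y = gen_phenotype(truth, beta, noise_sd=pheno_noise, seed=seed + 10_000)
    return {"views": views, "truth": truth, "phenotype": y}


SCENARIOS = {
    "two_view_1d": _scenario_two_view_1d,
    "grouped3": _scenario_grouped3,
    "fourview": _scenario_fourview,
}


def scenario(name: str, seed: int = 0) -> dict:
    """Instantiate a canned scenario; the dict always carries views + truth."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    out = SCENARIOS[name](seed)
    out["name"] = name
    out.setdefault("config", RunConfig(seed=seed))
    return out
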