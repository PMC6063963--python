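"""Bayesian per-mismatch penalty model of SaCas9 specificity.

The observed indel rate of guide ``j`` on a target with mismatch set ``M``
is modelled as the guide's on-target activity ``g_j`` attenuated by one
additive free-energy-like penalty per mismatch,

    I_{j,M} = g_j * exp(-sum_{k in M} ddG_k) + eps,   eps ~ Normal(0, sd)

or equivalently, in multiplicative form, ``I = g_j * prod_k f(pos_k, type_k)``
with ``f = exp(-ddG)`` in (0, 1]. Each mismatch is indexed by its
PAM-proximal position and its RNA:DNA base-pair class (12 non-Watson-Crick
pairs), and a separate penalty matrix ``f_L`` is fitted per spacer length
``L`` on disjoint training data. Penalties carry an exponential prior
(mean beta = 1, enforcing non-negativity and shrinkage); guide activities
are constrained to [0, 1].

Two fitting modes are provided: ``map`` (penalised maximum a posteriori via
L-BFGS-B, deterministic) and ``mcmc`` (Hamiltonian Monte Carlo over the
unconstrained reparameterisation, with R-hat convergence diagnostics).
The fitted matrix scores and ranks candidate off-target sites as the plain
product of per-mismatch factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dna import complement
from .hmc import sample_hmc

__all__ = [
    "MISMATCH_TYPES",
    "MismatchDescriptor",
    "PenaltyMatrix",
    "ModelConfig",
    "IndelObservation",
    "FitResult",
    "featurize",
    "predict",
    "build_observations",
    "fit",
    "check_convergence",
    "specificity_score",
    "rank_off_targets",
]

_WC = {"A": "T", "C": "G", "G": "C", "U": "A"}  # rna base -> its DNA partner

#: the 12 non-complementary rna:dna pairs, in fixed display order
MISMATCH_TYPES: tuple[tuple[str, str], ...] = tuple(
    (r, d) for r in "ACGU" for d in "ACGT" if _WC[r] != d
)
_TYPE_INDEX = {pair: i for i, pair in enumerate(MISMATCH_TYPES)}


class MismatchDescriptor(NamedTuple):
    position: int  # 1-based, PAM-proximal
    rna_base: str  # spacer base, RNA alphabet
    dna_base: str  # target-strand base the spacer base faces (template strand)
    type_index: int


def featurize(spacer: str, target: str) -> list[MismatchDescriptor]:
    """Mismatch descriptors for a spacer/protospacer pair of equal length.

    Positions are numbered from the PAM (position 1 = PAM-proximal). The
    DNA base reported is on the strand the guide RNA base-pairs with, i.e.
    the complement of the protospacer base, so a matched position forms a
    Watson-Crick rna:dna pair and never yields a descriptor. Bulged pairs
    (unequal lengths) are outside the model and rejected.
    """
    if len(spacer) != len(target):
        raise ValueError(
            f"spacer ({len(spacer)} nt) and target ({len(target)} nt) differ in length; "
            "bulged pairs are out of model scope"
        )
    L = len(spacer)
    out = []
    for idx, (s, t) in enumerate(zip(spacer, target)):
        if s == t:
            continue
        rna = "U" if s == "T" else s
        dna = complement(t)
        out.append(MismatchDescriptor(L - idx, rna, dna, _TYPE_INDEX[(rna, dna)]))
    return out


@dataclass
class PenaltyMatrix:
    """Per-length matrix of multiplicative penalties f in (0,1], indexed
    by (PAM-proximal position 1..L, mismatch type 0..11)."""

    length: int
    f: np.ndarray  # (L, 12)

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (self.length, len(MISMATCH_TYPES)):
            raise ValueError(f"f must have shape ({self.length}, {len(MISMATCH_TYPES)})")
        if (self.f <= 0).any() or (self.f > 1).any():
            raise ValueError("penalties must lie in (0, 1]")

    @property
    def ddg(self) -> np.ndarray:
        return -np.log(self.f)

    def value(self, position: int, type_index: int) -> float:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return float(self.f[position - 1, type_index])

    def to_frame(self, interval: Optional[np.ndarray] = None) -> pd.DataFrame:
        rows = []
        for p in range(self.length):
            for t, (rna, dna) in enumerate(MISMATCH_TYPES):
                row = {
                    "length": self.length,
                    "position": p + 1,
                    "rna_base": rna,
                    "dna_base": dna,
                    "f": self.f[p, t],
                    "ddg": -np.log(self.f[p, t]),
                }
                if interval is not None:
                    row["f_lo"], row["f_hi"] = interval[p, t]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path, interval: Optional[np.ndarray] = None) -> None:
        self.to_frame(interval).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PenaltyMatrix":
        L = int(df["length"].iloc[0])
        f = np.ones((L, len(MISMATCH_TYPES)))
        for _, row in df.iterrows():
            f[int(row["position"]) - 1, _TYPE_INDEX[(row["rna_base"], row["dna_base"])]] = row["f"]
        return cls(L, f)

    @classmethod
    def from_tsv(cls, path) -> "PenaltyMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def predict(g: float, descriptors: Sequence[MismatchDescriptor], penalty: PenaltyMatrix) -> float:
    """Predicted indel rate g * prod f(pos, type); equals g for an empty set."""
    out = float(g)
    for d in descriptors:
        out *= penalty.value(d.position, d.type_index)
    return out


@dataclass(frozen=True)
class ModelConfig:
    beta: float = 1.0  # exponential prior mean on ddG
    error_sd: float = 0.1  # Gaussian observation noise (replicate-derived)
    n_chains: int = 8
    n_samples: int = 1500  # per chain, warmup included
    n_warmup: int = 500
    rhat_threshold: float = 1.1
    mode: str = "map"  # "map" | "mcmc"
    seed: int = 0

    def __post_init__(self):
        if self.n_warmup >= self.n_samples:
            raise ValueError("n_warmup must be < n_samples")
        if self.error_sd <= 0 or self.beta <= 0:
            raise ValueError("error_sd and beta must be positive")
        if self.mode not in ("map", "mcmc"):
            raise ValueError(f"unknown mode {self.mode!r}")


class IndelObservation(NamedTuple):
    guide: object  # guide identifier (e.g. group_id)
    descriptors: tuple[MismatchDescriptor, ...]
    rate: float


@dataclass
class FitResult:
    penalty: PenaltyMatrix
    guide_activity: pd.DataFrame  # guide, g (posterior mean / MAP), g_lo, g_hi
    diagnostics: dict
    converged: Optional[bool]  # None in map mode
    prior_dominated: frozenset  # (position, type_index) cells with no data
    f_interval: Optional[np.ndarray] = None  # (L, 12, 2) credible bounds, mcmc only

    @property
    def mode(self) -> str:
        return self.diagnostics["mode"]


def build_observations(
    rates: pd.DataFrame, design: pd.DataFrame, length: int
) -> list[IndelObservation]:
    """Join quantified rates with the design and featurize, for one spacer length.

    Only mismatch-class members (matched, single/double mismatch, double
    transversion) with a finite rate and not flagged excluded enter the fit;
    bulged and scrambled members are outside the model.
    """
    cols = ["member_id", "group_id", "spacer", "spacer_length", "category", "target"]
    overlap = [c for c in cols if c != "member_id" and c in rates.columns]
    df = rates.drop(columns=overlap).merge(design[cols], on="member_id", how="inner")
    keep_cat = {"matched", "single_mismatch", "double_mismatch", "double_transversion"}
    df = df[
        (df["spacer_length"] == length)
        & df["category"].isin(keep_cat)
        & df["indel_rate"].notna()
    ]
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    obs = []
    for _, row in df.iterrows():
        desc = tuple(featurize(row["spacer"], row["target"]))
        obs.append(IndelObservation(row["group_id"], desc, float(row["indel_rate"])))
    return obs


# --- fitting --------------------------------------------------------------


def _design_matrices(observations: Sequence[IndelObservation], L: int):
    guides = sorted({o.guide for o in observations})
    gidx_of = {g: i for i, g in enumerate(guides)}
    n_cells = L * len(MISMATCH_TYPES)
    X = np.zeros((len(observations), n_cells), dtype=np.int8)
    gidx = np.empty(len(observations), dtype=np.int64)
    y = np.empty(len(observations))
    for i, o in enumerate(observations):
        gidx[i] = gidx_of[o.guide]
        y[i] = o.rate
        for d in o.descriptors:
            if d.position > L:
                raise ValueError(f"descriptor position {d.position} exceeds length {L}")
            X[i, (d.position - 1) * len(MISMATCH_TYPES) + d.type_index] += 1
    return guides, gidx, X, y


def fit(
    observations: Sequence[IndelObservation],
    length: int,
    config: ModelConfig = ModelConfig(),
) -> FitResult:
    """Fit guide activities and the per-mismatch penalty matrix for one length.

    Guides lacking a matched (empty mismatch set) observation are flagged
    weakly identified: their activity is informed only through mismatched
    observations. Penalty cells with no covering observation are reported
    prior-dominated (MAP pins them at the prior mode ddG = 0; MCMC returns
    the exponential prior itself).
    """
    if not observations:
        raise ValueError("no observations to fit")
    guides, gidx, X, y = _design_matrices(observations, length)
    n_g, n_cells = len(guides), X.shape[1]
    sd, beta = config.error_sd, config.beta
    covered = X.any(axis=0)
    prior_dominated = frozenset(
        (c // len(MISMATCH_TYPES) + 1, c % len(MISMATCH_TYPES))
        for c in np.nonzero(~covered)[0]
    )
    has_matched = {o.guide for o in observations if not o.descriptors}
    weak = [g for g in guides if g not in has_matched]

    # matched-rate initialisation for g
    g0 = np.full(n_g, 0.5)
    for o in observations:
        if not o.descriptors:
            g0[guides.index(o.guide)] = np.clip(o.rate, 0.01, 0.99)

    if config.mode == "map":
        res = _fit_map(gidx, X, y, n_g, n_cells, g0, sd, beta)
        g_hat, ddg_hat = res
        f_hat = np.exp(-ddg_hat).reshape(length, len(MISMATCH_TYPES))
        penalty = PenaltyMatrix(length, np.clip(f_hat, 1e-12, 1.0))
        guide_df = pd.DataFrame(
            {"guide": guides, "g": g_hat, "g_lo": np.nan, "g_hi": np.nan,
             "weakly_identified": [g in weak for g in guides]}
        )
        diags = {"mode": "map", "n_obs": len(y), "n_guides": n_g}
        return FitResult(penalty, guide_df, diags, None, prior_dominated)

    return _fit_mcmc(
        guides, gidx, X, y, n_g, n_cells, g0, length, weak, prior_dominated, config
    )


def _fit_map(gidx, X, y, n_g, n_cells, g0, sd, beta):
    Xf = X.astype(float)

    def objective(theta):
        g, d = theta[:n_g], theta[n_g:]
        atten = np.exp(-(Xf @ d))
        mu = g[gidx] * atten
        r = mu - y
        val = 0.5 * np.sum(r * r) / sd**2 + d.sum() / beta
        grad_g = np.bincount(gidx, weights=r * atten, minlength=n_g) / sd**2
        grad_d = -(Xf.T @ (r * mu)) / sd**2 + 1.0 / beta
        return val, np.concatenate([grad_g, grad_d])

    theta0 = np.concatenate([g0, np.full(n_cells, 0.1)])
    bounds = [(1e-6, 1.0)] * n_g + [(0.0, 50.0)] * n_cells
    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
    )
    return res.x[:n_g], res.x[n_g:]


def _fit_mcmc(guides, gidx, X, y, n_g, n_cells, g0, length, weak, prior_dominated, config):
    import arviz as az

    sd, beta = config.error_sd, config.beta
    Xf = X.astype(float)
    dim = n_g + n_cells

    # unconstrained parameterisation: g = sigmoid(v) (uniform prior on [0,1]
    # plus Jacobian), ddG = exp(u) (exponential prior, mean beta, plus Jacobian)
    def logp_grad(theta):
        v, u = theta[:n_g], theta[n_g:]
        g = special.expit(v)
        d = np.exp(u)
        atten = np.exp(-(Xf @ d))
        mu = g[gidx] * atten
        r = y - mu
        logp = -0.5 * np.sum(r * r) / sd**2 - d.sum() / beta + u.sum()
        # log g + log(1-g), computed stably in the unconstrained variable
        logp -= np.sum(np.logaddexp(0.0, -v) + np.logaddexp(0.0, v))
        dL_dg = np.bincount(gidx, weights=(r / sd**2) * atten, minlength=n_g)
        grad_v = dL_dg * g * (1 - g) + (1 - 2 * g)
        dL_dd = -(Xf.T @ ((r / sd**2) * mu))
        grad_u = (dL_dd - 1.0 / beta) * d + 1.0
        return logp, np.concatenate([grad_v, grad_u])

    master = np.random.default_rng(config.seed)
    chain_draws = np.empty((config.n_chains, config.n_samples - config.n_warmup, dim))
    accept = np.empty(config.n_chains)
    steps = np.empty(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        init = rng.uniform(-2, 2, dim)
        draws, acc, eps = sample_hmc(
            logp_grad, init, config.n_samples, config.n_warmup, rng
        )
        chain_draws[c], accept[c], steps[c] = draws, acc, eps

    g_draws = special.expit(chain_draws[:, :, :n_g])
    d_draws = np.exp(chain_draws[:, :, n_g:])
    f_draws = np.exp(-d_draws)

    ds = az.convert_to_dataset({"g": g_draws, "ddg": d_draws})
    rhat = az.rhat(ds)
    max_rhat = float(
        max(rhat["g"].values.max() if n_g else 1.0, rhat["ddg"].values.max())
    )
    converged = bool(max_rhat < config.rhat_threshold)

    f_mean = f_draws.mean(axis=(0, 1)).reshape(length, len(MISMATCH_TYPES))
    f_q = np.quantile(f_draws, [0.025, 0.975], axis=(0, 1))
    f_interval = np.stack(
        [f_q[0].reshape(length, -1), f_q[1].reshape(length, -1)], axis=-1
    )
    g_mean = g_draws.mean(axis=(0, 1))
    g_lo, g_hi = np.quantile(g_draws, [0.025, 0.975], axis=(0, 1))
    penalty = PenaltyMatrix(length, np.clip(f_mean, 1e-12, 1.0))
    guide_df = pd.DataFrame(
        {"guide": guides, "g": g_mean, "g_lo": g_lo, "g_hi": g_hi,
         "weakly_identified": [g in weak for g in guides]}
    )
    diags = {
        "mode": "mcmc",
        "n_obs": len(y),
        "n_guides": n_g,
        "ddg_posterior_mean": d_draws.mean(axis=(0, 1)).reshape(length, -1),
        "max_rhat": max_rhat,
        "rhat_g": rhat["g"].values,
        "rhat_ddg": rhat["ddg"].values,
        "accept_rate": accept,
        "step_size": steps,
    }
    return FitResult(penalty, guide_df, diags, converged, prior_dominated, f_interval)


def check_convergence(fit_result: FitResult, config: ModelConfig = ModelConfig()) -> Optional[bool]:
    """True iff every parameter's R-hat is below the threshold; None for MAP fits
    (the diagnostic is undefined without chains)."""
    if fit_result.mode != "mcmc":
        return None
    if config.n_chains < 2:
        raise ValueError("R-hat requires at least two chains")
    return bool(fit_result.diagnostics["max_rhat"] < config.rhat_threshold)


# --- scoring --------------------------------------------------------------


def specificity_score(
    spacer: str, candidate_site: str, penalty: PenaltyMatrix
) -> Optional[float]:
    """Product of per-mismatch penalties for a same-length candidate site.

    1.0 for a perfect match; adding a mismatch can never raise the score.
    Bulged candidates (length mismatch) get no score.
    """
    if len(candidate_site) != len(spacer):
        return None
    return predict(1.0, featurize(spacer, candidate_site), penalty)


def rank_off_targets(
    spacer: str,
    candidates: Sequence[str] | pd.DataFrame,
    penalty: PenaltyMatrix,
    activities: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Score candidate sites and order them by decreasing predicted activity.

    Ties break by fewer mismatches then lexicographic site, so the ranking
    is deterministic. When measured activities are supplied (one per
    candidate, e.g. GUIDE-seq read fractions), the Spearman rank
    correlation between scores and activities is returned alongside.
    """
    if isinstance(candidates, pd.DataFrame):
        sites = candidates["site"].tolist()
        if activities is None and "activity" in candidates.columns:
            activities = candidates["activity"].tolist()
    else:
        sites = list(candidates)
    rows = []
    for i, site in enumerate(sites):
        score = specificity_score(spacer, site, penalty)
        n_mm = len(featurize(spacer, site)) if score is not None else None
        rows.append(
            {
                "site": site,
                "score": score,
                "n_mismatches": n_mm,
                "reason": None if score is not None else "length mismatch (bulge)",
                "activity": activities[i] if activities is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    scored = df[df["score"].notna()].sort_values(
        ["score", "n_mismatches", "site"], ascending=[False, True, True]
    )
    unscored = df[df["score"].isna()]
    out = pd.concat([scored, unscored], ignore_index=True)
    rho = None
    ok = out["score"].notna() & out["activity"].notna()
    if activities is not None and ok.sum() >= 3:
        rho = float(stats.spearmanr(out.loc[ok, "score"], out.loc[ok, "activity"]).statistic)
    return out, rho
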