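"""Bayesian admixture-proportion estimation by Gibbs MCMC.

This is the classic Structure admixture model: each of an individual's allele
copies originates from one of K clusters; individual *i* has ancestry
proportions Q_i (Dirichlet(alpha) prior) and cluster *k* has per-locus
derived-allele frequencies f_kl.  Two frequency priors are available:

* ``uncorrelated`` — f_kl ~ Beta(lambda, lambda) independently (conjugate,
  pure Gibbs);
* ``correlated`` (F-model, the default) — cluster frequencies drift around a
  shared ancestral frequency p_l:  f_kl ~ Beta(p_l (1-F_k)/F_k,
  (1-p_l)(1-F_k)/F_k), with per-cluster drift parameters F_k (Gamma prior)
  and p_l (uniform prior) updated by Metropolis-Hastings inside the Gibbs
  sweep.

``AdmixtureModel(...).fit(...)`` returns :class:`AdmixtureResults` holding
posterior mean ancestry Q with equal-tailed 90% intervals (5th/95th
percentiles of the retained trace), drift estimates, the alpha trace, and
multi-chain agreement diagnostics.  Cluster labels are aligned across the
trace by greedy permutation matching of the cluster frequency vectors to a
running reference, which resolves label switching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .genio import GenotypeMatrix


class AdmixtureError(ValueError):
    pass


_EPS = 1e-12


@dataclass
class AdmixtureConfig:
    """Run parameters for the admixture sampler (used by the pipeline/CLI)."""

    k: int = 2
    burnin: int = 10_000
    reps: int = 20_000
    model: str = "correlated"
    alpha_mode: str = "fixed"
    alpha_init: float = 1.0
    lam: float = 1.0
    f_prior_shape: float = 2.0
    f_prior_scale: float = 0.05
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise AdmixtureError("K must be >= 1")
        if self.burnin < 0 or self.reps < 0:
            raise AdmixtureError("burnin and reps must be >= 0")
        if self.model not in ("correlated", "uncorrelated"):
            raise AdmixtureError(f"unknown model {self.model!r}")
        if self.alpha_mode not in ("infer", "fixed"):
            raise AdmixtureError(f"unknown alpha_mode {self.alpha_mode!r}")


@dataclass
class _ChainState:
    """Latent state of one Gibbs chain."""

    q: np.ndarray  # (S, K) ancestry proportions
    fr: np.ndarray  # (K, L) cluster derived-allele frequencies
    f_drift: np.ndarray  # (K,) drift parameters (correlated model)
    p_anc: np.ndarray  # (L,) ancestral frequencies (correlated model)
    alpha: float
    steps: dict = field(default_factory=lambda: {"f": 0.05, "F": 0.02, "p": 0.05, "a": 0.05})
    accept: dict = field(default_factory=dict)


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _EPS, 1.0 - _EPS)


def init_chain(
    rng: np.random.Generator, xd: np.ndarray, tot: np.ndarray, k: int,
    alpha: float, lam: float, f_shape: float, f_scale: float,
    freq_init: str = "seed-samples",
) -> _ChainState:
    """Draw the initial chain state.

    ``xd`` are per-sample/locus derived-copy counts and ``tot`` the total
    copies contributed (2, or 0 for a missing genotype).  Q rows come from
    Dirichlet(alpha) and drift/ancestral parameters from their priors.
    Cluster frequencies are seeded from K distinct randomly chosen samples'
    smoothed observed frequencies (``freq_init="seed-samples"``, the
    default): an overdispersed, data-informed start that keeps the chain out
    of the metastable symmetric state where every cluster mirrors the pooled
    frequencies.  ``freq_init="prior"`` draws them from the drift prior
    instead.
    """
    s, l = xd.shape
    q = rng.dirichlet(np.full(k, alpha), size=s)
    p_anc = _clip01(rng.uniform(size=l))
    f_drift = _clip01(rng.gamma(f_shape, f_scale, size=k))
    if freq_init == "seed-samples" and s >= k:
        picks = rng.choice(s, size=k, replace=False)
        fr = _clip01((xd[picks] + 0.5) / (tot[picks] + 1.0))
    elif freq_init in ("prior", "seed-samples"):
        c = (1.0 - f_drift) / f_drift
        fr = _clip01(
            rng.beta(p_anc[None, :] * c[:, None], (1.0 - p_anc[None, :]) * c[:, None])
        )
    else:
        raise AdmixtureError(f"unknown freq_init {freq_init!r}")
    return _ChainState(q=_clip01(q), fr=fr, f_drift=f_drift, p_anc=p_anc, alpha=alpha)


def assign_copies(
    rng: np.random.Generator, xd: np.ndarray, tot: np.ndarray, q: np.ndarray, fr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the cluster of origin of every allele copy.

    A derived copy of sample *i* at locus *l* goes to cluster *k* with
    probability proportional to q_ik f_kl (ancestral copies: q_ik (1-f_kl)).
    Returns ``(d_kl, a_kl, n_ik)``: derived / ancestral copy counts per
    cluster-locus, and total copies per sample-cluster.
    """
    s, l = xd.shape
    k = q.shape[1]
    d_by_k = np.zeros((k, s, l), dtype=np.int64)
    a_by_k = np.zeros((k, s, l), dtype=np.int64)
    for counts, w_f in ((d_by_k, fr), (a_by_k, 1.0 - fr)):
        w = q.T[:, :, None] * w_f[:, None, :]  # (K, S, L)
        tail = w[::-1].cumsum(axis=0)[::-1]
        rem = (xd if counts is d_by_k else tot - xd).astype(np.int64)
        for kk in range(k - 1):
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(tail[kk] > 0, w[kk] / tail[kk], 0.0)
            draw = rng.binomial(rem, np.clip(p, 0.0, 1.0))
            counts[kk] = draw
            rem = rem - draw
        counts[k - 1] = rem
    d_kl = d_by_k.sum(axis=1)
    a_kl = a_by_k.sum(axis=1)
    n_ik = (d_by_k + a_by_k).sum(axis=2).T  # (S, K)
    return d_kl, a_kl, n_ik


def update_q(
    rng: np.random.Generator, n_ik: np.ndarray, alpha: float
) -> np.ndarray:
    """Conjugate Dirichlet update: Q_i ~ Dirichlet(alpha + n_i1..n_iK)."""
    g = rng.standard_gamma(alpha + n_ik)
    tot = g.sum(axis=1, keepdims=True)
    bad = tot[:, 0] <= 0
    if bad.any():
        g[bad] = 1.0
        tot = g.sum(axis=1, keepdims=True)
    return _clip01(g / tot)


def update_freqs_uncorrelated(
    rng: np.random.Generator, d_kl: np.ndarray, a_kl: np.ndarray, lam: float
) -> np.ndarray:
    """Conjugate Beta update of cluster frequencies."""
    return _clip01(rng.beta(lam + d_kl, lam + a_kl))


def _bn_shapes(p_anc: np.ndarray, f_drift: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = (1.0 - f_drift) / f_drift  # (K,)
    return p_anc[None, :] * c[:, None], (1.0 - p_anc[None, :]) * c[:, None]


def update_freqs_correlated(
    rng: np.random.Generator, state: _ChainState, d_kl: np.ndarray, a_kl: np.ndarray
) -> float:
    """MH update of every f_kl under the drift prior; returns acceptance rate."""
    c1, c2 = _bn_shapes(state.p_anc, state.f_drift)
    f = state.fr
    prop = f + rng.normal(0.0, state.steps["f"], size=f.shape)
    inside = (prop > 0.0) & (prop < 1.0)
    prop_c = np.where(inside, prop, f)
    logr = (d_kl + c1 - 1.0) * (np.log(prop_c) - np.log(f)) + (
        a_kl + c2 - 1.0
    ) * (np.log1p(-prop_c) - np.log1p(-f))
    accept = inside & (np.log(rng.uniform(size=f.shape)) < logr)
    state.fr = np.where(accept, prop_c, f)
    return float(accept.mean())


def _drift_loglik(fr_k: np.ndarray, p_anc: np.ndarray, f: float) -> float:
    c = (1.0 - f) / f
    c1 = p_anc * c
    c2 = (1.0 - p_anc) * c
    return float(
        ((c1 - 1.0) * np.log(fr_k) + (c2 - 1.0) * np.log1p(-fr_k) - betaln(c1, c2)).sum()
    )


def update_drift(
    rng: np.random.Generator, state: _ChainState, shape: float, scale: float
) -> float:
    """MH update of each cluster's drift parameter F_k (Gamma prior)."""
    acc = 0
    for k in range(state.fr.shape[0]):
        f = state.f_drift[k]
        prop = f + rng.normal(0.0, state.steps["F"])
        if not (0.0 < prop < 1.0):
            continue
        logr = (
            _drift_loglik(state.fr[k], state.p_anc, prop)
            - _drift_loglik(state.fr[k], state.p_anc, f)
            + (shape - 1.0) * (np.log(prop) - np.log(f))
            - (prop - f) / scale
        )
        if np.log(rng.uniform()) < logr:
            state.f_drift[k] = prop
            acc += 1
    return acc / state.fr.shape[0]


def update_ancestral(rng: np.random.Generator, state: _ChainState) -> float:
    """MH update of the shared ancestral frequencies p_l (uniform prior)."""
    p = state.p_anc
    prop = p + rng.normal(0.0, state.steps["p"], size=p.shape)
    inside = (prop > 0.0) & (prop < 1.0)
    prop_c = np.where(inside, prop, p)
    c = (1.0 - state.f_drift) / state.f_drift  # (K,)

    def loglik(pa: np.ndarray) -> np.ndarray:
        c1 = pa[None, :] * c[:, None]
        c2 = (1.0 - pa[None, :]) * c[:, None]
        terms = (
            (c1 - 1.0) * np.log(state.fr)
            + (c2 - 1.0) * np.log1p(-state.fr)
            - betaln(c1, c2)
        )
        return terms.sum(axis=0)

    logr = loglik(prop_c) - loglik(p)
    accept = inside & (np.log(rng.uniform(size=p.shape)) < logr)
    state.p_anc = np.where(accept, prop_c, p)
    return float(accept.mean())


def update_alpha(rng: np.random.Generator, state: _ChainState, alpha_max: float = 10.0) -> float:
    """MH update of the Dirichlet concentration alpha, uniform prior on (0, alpha_max]."""
    s, k = state.q.shape
    a = state.alpha
    prop = a + rng.normal(0.0, state.steps["a"])
    if not (0.0 < prop <= alpha_max):
        return 0.0
    logq = np.log(state.q).sum()
    def lp(x: float) -> float:
        return s * (gammaln(k * x) - k * gammaln(x)) + (x - 1.0) * logq
    if np.log(rng.uniform()) < lp(prop) - lp(a):
        state.alpha = prop
        return 1.0
    return 0.0


def gibbs_sweep(
    rng: np.random.Generator,
    state: _ChainState,
    xd: np.ndarray,
    tot: np.ndarray,
    model: str = "correlated",
    lam: float = 1.0,
    f_prior: tuple[float, float] = (2.0, 0.05),
    alpha_mode: str = "fixed",
) -> dict:
    """One full Gibbs sweep; returns MH acceptance rates for adaptation."""
    d_kl, a_kl, n_ik = assign_copies(rng, xd, tot, state.q, state.fr)
    rates: dict[str, float] = {}
    if model == "uncorrelated":
        state.fr = update_freqs_uncorrelated(rng, d_kl, a_kl, lam)
    else:
        rates["f"] = update_freqs_correlated(rng, state, d_kl, a_kl)
        rates["F"] = update_drift(rng, state, *f_prior)
        rates["p"] = update_ancestral(rng, state)
    state.q = update_q(rng, n_ik, state.alpha)
    if alpha_mode == "infer" and state.q.shape[1] > 1:
        rates["a"] = update_alpha(rng, state)
    state.accept = rates
    return rates


def _best_permutation(fr: np.ndarray, ref: np.ndarray) -> tuple[int, ...]:
    k = fr.shape[0]
    if k == 1:
        return (0,)
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(k)):
        cost = float(((fr[list(perm)] - ref) ** 2).sum())
        if cost < best_cost:
            best, best_cost = perm, cost
    return best


def _apply_permutation(state: _ChainState, perm: tuple[int, ...]) -> None:
    idx = list(perm)
    state.fr = state.fr[idx]
    state.f_drift = state.f_drift[idx]
    state.q = state.q[:, idx]


class AdmixtureModel:
    """Structure-style admixture model for a biallelic genotype matrix.

    Parameters
    ----------
    data
        A :class:`~introkit.genio.GenotypeMatrix` (biallelic loci only) or a
        plain ``(n_samples, n_loci)`` dosage array (NaN / -1 = missing).
    k
        Number of ancestry clusters.
    model
        ``"correlated"`` (F-model, default) or ``"uncorrelated"``.
    alpha_mode, alpha
        Hold the Dirichlet concentration fixed at ``alpha`` (default 1.0 — a
        uniform prior on each ancestry vector) or infer it by MH on (0, 10].
        Inference is faithful to the classic tool but at small locus counts
        the fitted concentration drops below 1 and its boundary spike absorbs
        small admixture fractions of single individuals; the uniform prior
        gives near-unbiased recovery there (see the methods note).
    lam
        Beta(lambda, lambda) frequency prior of the uncorrelated model.
    f_prior
        (shape, scale) of the Gamma prior on the drift parameters F_k.
    """

    def __init__(
        self,
        data,
        k: int = 2,
        model: str = "correlated",
        alpha_mode: str = "fixed",
        alpha: float = 1.0,
        lam: float = 1.0,
        f_prior: tuple[float, float] = (2.0, 0.05),
        sample_ids: list[str] | None = None,
        populations: dict[str, str] | None = None,
    ) -> None:
        if isinstance(data, GenotypeMatrix):
            if not data.is_biallelic.all():
                raise AdmixtureError("matrix contains multiallelic loci")
            dos = data.dosages
            sample_ids = list(data.sample_ids)
            populations = populations or data.populations
        else:
            dos = np.asarray(data, dtype=float)
            dos = np.where(dos < 0, np.nan, dos)
        if k < 1:
            raise AdmixtureError("K must be >= 1")
        if model not in ("correlated", "uncorrelated"):
            raise AdmixtureError(f"unknown model {model!r}")
        if alpha_mode not in ("infer", "fixed"):
            raise AdmixtureError(f"unknown alpha_mode {alpha_mode!r}")
        missing = np.isnan(dos)
        self.xd = np.where(missing, 0, dos).astype(np.int64)
        self.tot = np.where(missing, 0, 2).astype(np.int64)
        self.k = k
        self.model = model
        self.alpha_mode = alpha_mode
        self.alpha0 = alpha
        self.lam = lam
        self.f_prior = f_prior
        self.sample_ids = sample_ids or [f"s{i}" for i in range(dos.shape[0])]
        self.populations = populations

    @classmethod
    def from_genotype_matrix(cls, matrix: GenotypeMatrix, **kwargs) -> "AdmixtureModel":
        return cls(matrix, **kwargs)

    @classmethod
    def from_config(cls, matrix: GenotypeMatrix, config: AdmixtureConfig) -> "AdmixtureModel":
        return cls(
            matrix,
            k=config.k,
            model=config.model,
            alpha_mode=config.alpha_mode,
            alpha=config.alpha_init,
            lam=config.lam,
            f_prior=(config.f_prior_shape, config.f_prior_scale),
        )

    # -- sampling -----------------------------------------------------------

    def _run_chain(
        self, rng: np.random.Generator, burnin: int, reps: int, thin: int,
        align_labels: bool,
    ) -> dict:
        state = init_chain(
            rng, self.xd, self.tot, self.k, self.alpha0, self.lam, *self.f_prior
        )
        sweep_kwargs = dict(
            model=self.model, lam=self.lam, f_prior=self.f_prior,
            alpha_mode=self.alpha_mode,
        )
        acc_hist: dict[str, list[float]] = {}
        for it in range(burnin):
            rates = gibbs_sweep(rng, state, self.xd, self.tot, **sweep_kwargs)
            for key, r in rates.items():
                acc_hist.setdefault(key, []).append(r)
            if (it + 1) % 25 == 0:  # step-size adaptation toward 20-50% acceptance
                for key, step_key in (("f", "f"), ("F", "F"), ("p", "p"), ("a", "a")):
                    hist = acc_hist.get(key)
                    if not hist:
                        continue
                    recent = float(np.mean(hist[-25:]))
                    if recent > 0.5:
                        state.steps[step_key] *= 1.3
                    elif recent < 0.2:
                        state.steps[step_key] /= 1.3
        q_trace, fr_ref, alpha_trace, f_trace = [], None, [], []
        n_kept = 0
        for it in range(reps):
            gibbs_sweep(rng, state, self.xd, self.tot, **sweep_kwargs)
            if it % thin:
                continue
            if align_labels:
                if fr_ref is None:
                    fr_ref = state.fr.copy()
                else:
                    perm = _best_permutation(state.fr, fr_ref)
                    if perm != tuple(range(self.k)):
                        _apply_permutation(state, perm)
                    n_kept += 1
                    fr_ref += (state.fr - fr_ref) / (n_kept + 1)
            q_trace.append(state.q.copy())
            alpha_trace.append(state.alpha)
            f_trace.append(state.f_drift.copy())
        return {
            "q_trace": np.array(q_trace),
            "alpha_trace": np.array(alpha_trace),
            "f_trace": np.array(f_trace),
            "fr_mean": fr_ref if fr_ref is not None else state.fr.copy(),
            "steps": dict(state.steps),
        }

    def fit(
        self,
        burnin: int = 10_000,
        reps: int = 20_000,
        thin: int = 1,
        seed: int = 0,
        n_chains: int = 1,
        align_labels: bool = True,
    ) -> "AdmixtureResults":
        """Run the Gibbs sampler and summarize the posterior.

        ``n_chains`` > 1 reruns the sampler from independent seeds and
        reports the maximum disagreement in posterior mean ancestry between
        chains (after matching cluster labels across chains) — the
        "run several times, same results" stability check.
        """
        if reps <= 0:
            raise AdmixtureError("reps must be > 0 (no posterior sample otherwise)")
        if burnin < 0 or thin < 1:
            raise AdmixtureError("burnin must be >= 0 and thin >= 1")
        chains = []
        for c in range(n_chains):
            rng = np.random.default_rng([10 + c, seed])
            chains.append(self._run_chain(rng, burnin, reps, thin, align_labels))
        # match cluster labels across chains through the frequency means
        ref = chains[0]["fr_mean"]
        for ch in chains[1:]:
            perm = _best_permutation(ch["fr_mean"], ref)
            idx = list(perm)
            ch["q_trace"] = ch["q_trace"][:, :, idx]
            ch["f_trace"] = ch["f_trace"][:, idx]
            ch["fr_mean"] = ch["fr_mean"][idx]
        q_means = np.array([ch["q_trace"].mean(axis=0) for ch in chains])
        disagreement = (
            float(np.abs(q_means - q_means[0]).max()) if n_chains > 1 else None
        )
        trace = np.concatenate([ch["q_trace"] for ch in chains], axis=0)
        alpha_trace = np.concatenate([ch["alpha_trace"] for ch in chains])
        f_trace = np.concatenate([ch["f_trace"] for ch in chains], axis=0)
        return AdmixtureResults(
            model=self,
            q_trace=trace,
            alpha_trace=alpha_trace,
            f_trace=f_trace,
            chain_disagreement=disagreement,
            n_chains=n_chains,
        )


class AdmixtureResults:
    """Posterior summaries of a fitted admixture model."""

    def __init__(
        self,
        model: AdmixtureModel,
        q_trace: np.ndarray,
        alpha_trace: np.ndarray,
        f_trace: np.ndarray,
        chain_disagreement: float | None,
        n_chains: int,
    ) -> None:
        self.model = model
        self.q_trace = q_trace
        self.alpha_trace = alpha_trace
        self.f_trace = f_trace
        self.chain_disagreement = chain_disagreement
        self.n_chains = n_chains
        self.q_mean = q_trace.mean(axis=0)
        self.q_lower = np.percentile(q_trace, 5, axis=0)
        self.q_upper = np.percentile(q_trace, 95, axis=0)
        self.f_mean = f_trace.mean(axis=0) if f_trace.size else None
        self.alpha_mean = float(alpha_trace.mean()) if alpha_trace.size else None
        self.alpha_sd = float(alpha_trace.std()) if alpha_trace.size else None

    @property
    def sample_ids(self) -> list[str]:
        return self.model.sample_ids

    def to_frame(self) -> pd.DataFrame:
        """Per-sample table: cluster means and 90% equal-tailed intervals."""
        k = self.model.k
        rows = []
        pops = self.model.populations or {}
        for i, s in enumerate(self.sample_ids):
            row: dict = {"sample": s, "population": pops.get(s, "")}
            for c in range(k):
                row[f"Q{c+1}"] = self.q_mean[i, c]
            for c in range(k):
                row[f"Q{c+1}_90CI"] = (
                    f"{self.q_lower[i, c]:.3f},{self.q_upper[i, c]:.3f}"
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def summary(self) -> str:
        lines = [
            "Admixture model posterior summary",
            f"  model: {self.model.model}, K={self.model.k}, "
            f"samples={len(self.sample_ids)}, loci={self.model.xd.shape[1]}",
            f"  retained draws: {self.q_trace.shape[0]} "
            f"({self.n_chains} chain{'s' if self.n_chains > 1 else ''})",
        ]
        if self.alpha_mean is not None and self.model.alpha_mode == "infer":
            lines.append(f"  alpha: {self.alpha_mean:.3f} (sd {self.alpha_sd:.3f})")
        if self.f_mean is not None and self.model.model == "correlated":
            lines.append(
                "  drift F: " + ", ".join(f"{f:.3f}" for f in self.f_mean)
            )
        if self.chain_disagreement is not None:
            lines.append(f"  max |dQ_mean| across chains: {self.chain_disagreement:.4f}")
        lines.append("")
        lines.append(self.to_frame().to_string(index=False, float_format="%.3f"))
        return "\n".join(lines)


def run_admixture(
    matrix: GenotypeMatrix, config: AdmixtureConfig, n_chains: int = 1
) -> AdmixtureResults:
    """Functional wrapper: configure, fit, and return the results object."""
    model = AdmixtureModel.from_config(matrix, config)
    return model.fit(
        burnin=config.burnin,
        reps=config.reps,
        thin=config.thin,
        seed=config.seed,
        n_chains=n_chains,
    )
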