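"""Product-multinomial likelihood and maximum-likelihood fitting.

Each capture history contributes the probability of its observation
sequence after first release, conditional on release in the observed state.
The probability is evaluated by the standard hidden-Markov forward
recursion over the five states (four live + dead): propagate the state
distribution through the interval's transition block, then weight by the
observation (captured in state s: factor p at that state; not captured:
factor 1-p per live state, 1 for dead).

Fitting maximises the summed log-likelihood over the free parameters on
the logit scale with L-BFGS-B from several dispersed starts; standard
errors come from the inverse of a central-difference Hessian, mapped to
the probability scale by the delta method.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .data_model import ADULT, JUVENILE, CaptureHistory, Dataset, StudyDesign
from .model_spec import ModelSpec, ParameterIndex, build_parameter_index
from .transitions import (
    RateSet,
    block_for,
    block_kind,
    experienced_matrix,
    immature_matrix,
    juvenile_matrix,
)


class ImpossibleHistoryError(ValueError):
    """A history has probability zero under the model (infinite NLL)."""


# ---------------------------------------------------------------------------
# single-history NLL (reference implementation)
# ---------------------------------------------------------------------------

def history_nll(history: CaptureHistory, rates: RateSet, design: StudyDesign) -> float:
    """Negative log probability of one history after its release.

    Returns ``inf`` for a history that is impossible under the rates.
    """
    s = design.species.index(history.species)
    release = history.release_occasion
    v = np.zeros(5)
    v[history.release_state - 1] = 1.0
    ll = 0.0
    for t in range(release, design.n_occasions - 1):
        blk = block_for(history, rates, design, t)
        v = v @ blk.matrix
        obs = history.observations[t + 1]
        pvec = blk.recapture
        if obs:
            w = np.zeros(5)
            w[obs - 1] = pvec[obs - 1]
        else:
            w = np.append(1.0 - pvec, 1.0)
        v = v * w
        tot = v.sum()
        if tot <= 0.0:
            return np.inf
        ll += np.log(tot)
        v = v / tot
    return -ll


def dataset_nll(dataset: Dataset, rates: RateSet) -> float:
    return float(sum(history_nll(h, rates, dataset.design) for h in dataset.histories))


def dataset_deviance(dataset: Dataset, rates: RateSet) -> float:
    """-2 log-likelihood of the whole dataset (no saturated-model constant)."""
    return 2.0 * dataset_nll(dataset, rates)


# ---------------------------------------------------------------------------
# pooled, group-vectorised NLL used inside the optimiser
# ---------------------------------------------------------------------------

@dataclass
class _Group:
    species: int
    ageclass: str
    release: int
    cohort: int
    obs: np.ndarray     # (m, T) unique observation rows
    counts: np.ndarray  # (m,)
    init: np.ndarray    # (m,) release-state indices 0..3


def pool_dataset(dataset: Dataset) -> list[_Group]:
    """Group histories by (species, age class, release, cohort) and pool
    duplicate observation rows with multiplicities."""
    design = dataset.design
    buckets = defaultdict(lambda: defaultdict(int))
    for h in dataset.histories:
        s = design.species.index(h.species)
        release = h.release_occasion
        cohort = 0
        if h.age_at_marking == JUVENILE:
            cohort = design.cockchafer_flag(design.occasion_labels[release])
        buckets[(s, h.age_at_marking, release, cohort)][h.observations] += 1
    groups = []
    for (s, age, release, cohort), rows in sorted(buckets.items(), key=str):
        obs = np.array(sorted(rows), dtype=int)
        counts = np.array([rows[tuple(r)] for r in obs], dtype=float)
        groups.append(
            _Group(
                species=s,
                ageclass=age,
                release=release,
                cohort=cohort,
                obs=obs,
                counts=counts,
                init=obs[:, release] - 1,
            )
        )
    return groups


def _block_matrices(rates: RateSet, design: StudyDesign):
    """Cache of 5x5 matrices keyed by (kind, age, species, interval, cohort)."""
    cache: dict = {}

    def get(kind, a, s, t, coh):
        key = (kind, a, s, t, coh)
        if key not in cache:
            if kind == "juv":
                cache[key] = juvenile_matrix(
                    rates.phi_juv[s, 0, t],
                    rates.phi_juv[s, 1, t],
                    rates.natal[s, 0],
                    rates.natal[s, 1],
                    rates.alpha[0, s, 0, t, coh],
                    rates.alpha[0, s, 1, t, coh],
                )
            elif kind == "imm":
                cache[key] = immature_matrix(
                    rates.phi_ad[s, 0, t],
                    rates.phi_ad[s, 1, t],
                    rates.breeding[s, 0],
                    rates.breeding[s, 1],
                    rates.alpha[a - 1, s, 0, t, coh],
                    rates.alpha[a - 1, s, 1, t, coh],
                )
            else:
                cache[key] = experienced_matrix(
                    rates.phi_ad[s, 0, t],
                    rates.phi_ad[s, 1, t],
                    rates.breeding[s, 0],
                    rates.breeding[s, 1],
                )
        return cache[key]

    return get


def pooled_nll(groups: list[_Group], rates: RateSet, design: StudyDesign) -> float:
    """Total NLL over pooled groups; equals the sum of history_nll values."""
    T = design.n_occasions
    get_matrix = _block_matrices(rates, design)
    total = 0.0
    for g in groups:
        m = g.obs.shape[0]
        V = np.zeros((m, 5))
        V[np.arange(m), g.init] = 1.0
        ll = np.zeros(m)
        for t in range(g.release, T - 1):
            kind, a = block_kind(g.ageclass, g.release, t)
            M = get_matrix(kind, a, g.species, t, g.cohort)
            V = V @ M
            pvec = rates.p_vector(g.species, t + 1)
            obs = g.obs[:, t + 1]
            W = np.empty((m, 5))
            W[:, :4] = 1.0 - pvec
            W[:, 4] = 1.0
            seen = obs > 0
            if seen.any():
                W[seen] = 0.0
                W[seen, obs[seen] - 1] = pvec[obs[seen] - 1]
            V = V * W
            tot = V.sum(axis=1)
            if np.any(tot <= 0.0):
                return np.inf
            ll += np.log(tot)
            V = V / tot[:, None]
        total -= float(g.counts @ ll)
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Maximum-likelihood fit of one candidate model."""

    spec: ModelSpec
    index: ParameterIndex
    beta: np.ndarray
    estimates: RateSet
    se: RateSet | None
    deviance: float
    free_parameters: int
    converged: bool
    hessian_rank: int
    nll_trace: list[float]
    dataset_size: int
    name: str = ""

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.free_parameters

    def estimate(self, family: str, **axes):
        """(estimate, SE) of one parameter cell on the probability scale.

        ``family`` is one of ``phi_juv``, ``phi_ad``, ``alpha1..3``,
        ``natal_NR/RN``, ``breeding_NR/RN``, ``p``; axes select species
        (label or index) and, where relevant, colony/interval/occasion/
        status/cohort (defaults: first colony, first interval, cohort 0).
        """
        design = self.index.design
        s = axes.get("species", 0)
        if isinstance(s, str):
            s = design.species.index(s)
        c = axes.get("colony", 0)
        if isinstance(c, str):
            c = design.colonies.index(c)
        t = axes.get("interval", 0)
        coh = axes.get("cohort", 0)

        if family.startswith("natal") or family.startswith("breeding"):
            base = "natal" if family.startswith("natal") else "breeding"
            d = 0 if family.endswith("NR") else 1
            est = getattr(self.estimates, base)[s, d]
            se = getattr(self.se, base)[s, d] if self.se is not None else np.nan
            return float(est), float(se)
        if family == "p":
            occ = axes.get("occasion", 1)
            status = axes.get("status", 1)
            est = self.estimates.p[s, c, status, occ]
            se = self.se.p[s, c, status, occ] if self.se is not None else np.nan
            return float(est), float(se)
        if family.startswith("alpha"):
            age = int(family[-1])
            est = self.estimates.alpha[age - 1, s, c, t, coh]
            se = self.se.alpha[age - 1, s, c, t, coh] if self.se is not None else np.nan
            return float(est), float(se)
        if family in ("phi_juv", "phi_ad"):
            est = getattr(self.estimates, family)[s, c, t]
            se = getattr(self.se, family)[s, c, t] if self.se is not None else np.nan
            return float(est), float(se)
        raise KeyError(f"unknown parameter family {family!r}")

    def to_json(self, path=None) -> dict:
        out = {
            "name": self.name or self.spec.notation(),
            "deviance": self.deviance,
            "free_parameters": self.free_parameters,
            "aic": self.aic,
            "converged": self.converged,
            "hessian_rank": self.hessian_rank,
            "beta": [float(b) for b in self.beta],
            "param_names": self.index.param_names,
            "nll_trace": [float(x) for x in self.nll_trace],
            "dataset_size": self.dataset_size,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=1)
        return out


def _central_hessian(f, x, step=1e-4):
    k = x.size
    H = np.empty((k, k))
    hs = step * (1.0 + np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = hs[i]
            ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def fit(
    spec: ModelSpec,
    dataset: Dataset,
    starts: int = 5,
    seed: int = 0,
    tol: float = 1e-10,
    compute_se: bool = True,
    maxiter: int = 1000,
) -> FittedModel:
    """Maximum-likelihood fit of ``spec`` to ``dataset``.

    The optimiser runs from ``starts`` dispersed initial points (the first
    at logit 0, i.e. all probabilities 0.5); the best optimum is reported
    and the fit is flagged converged when the optimiser succeeded and the
    two best starts agree to 1e-4 in deviance.
    """
    design = dataset.design
    index = build_parameter_index(spec, design)
    groups = pool_dataset(dataset)

    base = index.resolve(np.zeros(index.n_free))
    if not np.isfinite(pooled_nll(groups, base, design)):
        bad = [
            h.individual_id
            for h in dataset.histories
            if not np.isfinite(history_nll(h, base, design))
        ]
        raise ImpossibleHistoryError(
            f"{len(bad)} histories are impossible under this model "
            f"(first few: {bad[:5]}); check state codes against the "
            "model's structural zeros"
        )

    def objective(beta):
        val = pooled_nll(groups, index.resolve(beta), design)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    x0s = [np.zeros(index.n_free)]
    x0s += [rng.normal(0.0, 1.0, index.n_free) for _ in range(max(0, starts - 1))]

    results = []
    for x0 in x0s:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-7, "maxiter": maxiter, "maxfun": 10 * maxiter * max(1, index.n_free)},
        )
        results.append(res)
    finals = sorted(r.fun for r in results)
    best = min(results, key=lambda r: r.fun)
    # convergence: optimiser success plus agreement of the two best starts
    # on the deviance scale
    agree = len(finals) < 2 or 2.0 * (finals[1] - finals[0]) <= 1e-4
    converged = bool(best.success)

    beta = best.x
    estimates = index.resolve(beta)
    se = None
    hessian_rank = 0
    if index.n_free:
        H = _central_hessian(objective, beta)
        hessian_rank = int(np.linalg.matrix_rank(H, tol=1e-6 * max(1.0, np.abs(H).max())))
        try:
            cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            cov = np.full((index.n_free, index.n_free), np.nan)
        if compute_se:
            se = index.resolve_se(beta, cov)
    elif compute_se:
        se = index.resolve_se(beta, np.zeros((0, 0)))

    return FittedModel(
        spec=spec,
        index=index,
        beta=beta,
        estimates=estimates,
        se=se,
        deviance=2.0 * float(best.fun),
        free_parameters=index.n_free,
        converged=converged and agree,
        hessian_rank=hessian_rank,
        nll_trace=[float(r.fun) for r in results],
        dataset_size=len(dataset),
        name=spec.notation(),
    )
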