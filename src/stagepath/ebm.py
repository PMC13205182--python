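"""Mixture of event-based models over irreversible binary events.

The generative picture: each subject belongs to one of C subtypes; a
subtype c is a fixed ordering S_c of the N events.  The subject sits at a
latent stage k in 0..N, meaning the first k events of its subtype's
ordering have occurred.  Observations are noisy indicators: a spurious
call arises with probability alpha when the event has not occurred, and a
missed call with probability beta when it has.  With a uniform stage
prior the single-subtype likelihood of a binary profile x is

    P(x | S) = 1/(N+1) * sum_{k=0}^{N}
               prod_{i<=k} Bern(x_{S(i)}; 1-beta) * prod_{i>k} Bern(x_{S(i)}; alpha)

and a cohort mixes subtypes with fractions f_c:  P(x) = sum_c f_c P(x|S_c).

Fitting is stochastic ascent: Metropolis MCMC over orderings (random
transpositions within one subtype at a time, or adjacent swaps), with
mixture fractions updated each sweep by EM-style responsibility means;
the best state visited is returned.  Noise rates are fixed
hyper-parameters, not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import BinaryMutationMatrix
from .io import write_json, read_json

__all__ = [
    "NoiseModel",
    "EventOrdering",
    "SubtypeModel",
    "AssignmentTable",
    "CVReport",
    "data_log_likelihood",
    "fit_model",
    "select_subtype_count",
    "assign_subjects",
]

_FRACTION_FLOOR = 1e-4


@dataclass(frozen=True)
class NoiseModel:
    """Observation error rates of the binary mutation calls.

    alpha: P(observe 1 | event not occurred); beta: P(observe 0 | occurred).
    """

    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 <= value < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {value}")


class EventOrdering:
    """An ordering of the N event names; position = 1-based event stage."""

    def __init__(self, events: list[str] | tuple[str, ...]):
        events = tuple(events)
        if len(set(events)) != len(events):
            raise ValueError("ordering contains duplicate events")
        self.events = events

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventOrdering) and self.events == other.events

    def __repr__(self) -> str:
        return f"EventOrdering({list(self.events)!r})"

    def positions(self) -> dict[str, int]:
        """Map event name -> 1-based stage at which the event occurs."""
        return {e: i + 1 for i, e in enumerate(self.events)}

    def stage_of(self, event: str) -> int:
        return self.positions()[event]


@dataclass
class SubtypeModel:
    """Fitted trajectory mixture: C orderings + fractions + noise model."""

    orderings: list[EventOrdering]
    fractions: np.ndarray
    noise: NoiseModel
    log_likelihood: float = np.nan
    mcmc_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.orderings) < 1:
            raise ValueError("need at least one subtype")
        if len(self.fractions) != len(self.orderings):
            raise ValueError("fractions and orderings length mismatch")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        events = set(self.orderings[0].events)
        for o in self.orderings[1:]:
            if set(o.events) != events:
                raise ValueError("all orderings must share one event set")

    @property
    def n_subtypes(self) -> int:
        return len(self.orderings)

    @property
    def event_names(self) -> list[str]:
        return list(self.orderings[0].events)

    def to_json(self, path: str | Path) -> None:
        write_json(
            {
                "orderings": [list(o.events) for o in self.orderings],
                "fractions": self.fractions.tolist(),
                "noise": {"alpha": self.noise.alpha, "beta": self.noise.beta},
                "log_likelihood": self.log_likelihood,
                "mcmc_summary": self.mcmc_summary,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeModel":
        d = read_json(path)
        return cls(
            orderings=[EventOrdering(o) for o in d["orderings"]],
            fractions=np.asarray(d["fractions"]),
            noise=NoiseModel(**d["noise"]),
            log_likelihood=d["log_likelihood"],
            mcmc_summary=d.get("mcmc_summary", {}),
        )


@dataclass
class AssignmentTable:
    """Per-sample subtype responsibilities and stage posteriors."""

    sample_ids: list[str]
    responsibilities: np.ndarray  # n x C, rows sum to 1
    stage_posteriors: np.ndarray  # n x (N+1) over stages 0..N, within MAP subtype
    map_subtype: np.ndarray  # int, 0-based subtype index
    map_stage: np.ndarray  # int, stage in 0..N (0 = no events yet)

    @property
    def p_subtype(self) -> np.ndarray:
        return self.responsibilities.max(axis=1)

    @property
    def p_stage(self) -> np.ndarray:
        return self.stage_posteriors.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n, c = self.responsibilities.shape
        df = pd.DataFrame(
            {
                "map_subtype": self.map_subtype,
                "map_stage": self.map_stage,
                "p_subtype": self.p_subtype,
                "p_stage": self.p_stage,
            },
            index=pd.Index(self.sample_ids, name="sample"),
        )
        for k in range(c):
            df[f"resp_subtype{k}"] = self.responsibilities[:, k]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class CVReport:
    """Held-out log-likelihoods per candidate subtype count."""

    candidates: list[int]
    fold_loglik: dict[int, list[float]]  # per-sample mean held-out ll per fold
    mean: dict[int, float]
    se: dict[int, float]
    chosen: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "C": self.candidates,
                "mean_heldout_loglik": [self.mean[c] for c in self.candidates],
                "se": [self.se[c] for c in self.candidates],
                "chosen": [c == self.chosen for c in self.candidates],
            }
        )


# ---------------------------------------------------------------------------
# likelihood machinery

def _log_bernoulli_terms(values: np.ndarray, noise: NoiseModel):
    """Per-entry log-probabilities under 'occurred' and 'not occurred'."""
    x = values.astype(bool)
    l_occ = np.where(x, np.log1p(-noise.beta), np.log(noise.beta) if noise.beta > 0 else -np.inf)
    l_not = np.where(x, np.log(noise.alpha) if noise.alpha > 0 else -np.inf, np.log1p(-noise.alpha))
    return l_occ, l_not


def _stage_loglik(l_occ: np.ndarray, l_not: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """n x (N+1) matrix of log P(x_j | stage k, ordering perm), flat stage prior excluded."""
    a = l_occ[:, perm]
    b = l_not[:, perm]
    n = a.shape[0]
    zeros = np.zeros((n, 1))
    cum_a = np.concatenate([zeros, np.cumsum(a, axis=1)], axis=1)
    # suffix sums computed directly so -inf terms (zero noise) stay well-defined
    suffix_b = np.concatenate(
        [np.cumsum(b[:, ::-1], axis=1)[:, ::-1], zeros], axis=1
    )
    return cum_a + suffix_b


def _subtype_loglik(l_occ, l_not, perm) -> np.ndarray:
    """log P(x_j | ordering), i.e. stage terms averaged over the uniform prior."""
    s = _stage_loglik(l_occ, l_not, perm)
    return logsumexp(s, axis=1) - np.log(s.shape[1])


def _check_events(matrix: BinaryMutationMatrix, model: SubtypeModel) -> None:
    have, want = set(matrix.event_names), set(model.event_names)
    if have != want:
        diff = sorted(have.symmetric_difference(want))
        raise ValueError(f"event sets differ between matrix and model: {diff}")


def _perms_for_model(matrix: BinaryMutationMatrix, model: SubtypeModel) -> list[np.ndarray]:
    col = {e: i for i, e in enumerate(matrix.event_names)}
    return [np.array([col[e] for e in o.events]) for o in model.orderings]


def data_log_likelihood(
    matrix: BinaryMutationMatrix, model: SubtypeModel
) -> tuple[np.ndarray, float]:
    """Per-sample mixture log-likelihoods and their total.

    Exact under the event-based construction: uniform stage prior over
    0..N within each subtype, subtypes mixed by the model fractions.
    """
    _check_events(matrix, model)
    l_occ, l_not = _log_bernoulli_terms(matrix.values, model.noise)
    per_subtype = np.stack(
        [_subtype_loglik(l_occ, l_not, p) for p in _perms_for_model(matrix, model)],
        axis=1,
    )
    with np.errstate(divide="ignore"):
        log_f = np.log(model.fractions)
    per_sample = logsumexp(per_subtype + log_f[None, :], axis=1)
    return per_sample, float(per_sample.sum())


# ---------------------------------------------------------------------------
# fitting

def _frequency_ordering(values: np.ndarray, event_names: list[str]) -> np.ndarray:
    """Column permutation: descending mutation frequency, ties by name."""
    freqs = values.mean(axis=0)
    order = sorted(range(len(event_names)), key=lambda i: (-freqs[i], event_names[i]))
    return np.array(order)


def _perturb(perm: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    perm = perm.copy()
    n = len(perm)
    for _ in range(n_swaps):
        i, j = rng.integers(0, n, size=2)
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def _init_orderings(
    values: np.ndarray,
    event_names: list[str],
    C: int,
    rng: np.random.Generator,
    start: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Greedy initialisation: cluster samples, order events by within-cluster
    frequency (descending = earlier stage); later restarts add random swaps."""
    n, N = values.shape
    base = _frequency_ordering(values, event_names)
    if C == 1:
        perm = base if start == 0 else _perturb(base, N, rng)
        return [perm], np.array([1.0])
    from scipy.cluster.vq import kmeans2

    seed = int(rng.integers(0, 2**31 - 1))
    try:
        _, labels = kmeans2(
            values.astype(float), C, minit="++", seed=seed, missing="warn"
        )
    except Exception:
        labels = rng.integers(0, C, size=n)
    perms, fracs = [], []
    for c in range(C):
        mask = labels == c
        if mask.sum() < 2:
            perm = _perturb(base, N, rng)
            frac = 1.0 / n
        else:
            perm = _frequency_ordering(values[mask], event_names)
            frac = mask.mean()
        if start > 0:
            perm = _perturb(perm, max(1, N // 4), rng)
        perms.append(perm)
        fracs.append(max(frac, _FRACTION_FLOOR))
    fracs = np.array(fracs)
    return perms, fracs / fracs.sum()


def _mixture_loglik(per_subtype: np.ndarray, fractions: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        log_f = np.log(fractions)
    return float(logsumexp(per_subtype + log_f[None, :], axis=1).sum())


def _responsibility_fractions(per_subtype: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_w = per_subtype + np.log(fractions)[None, :]
    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    new = np.exp(log_w).mean(axis=0)
    new = np.maximum(new, _FRACTION_FLOOR)
    return new / new.sum()


def fit_model(
    matrix: BinaryMutationMatrix,
    C: int,
    noise: NoiseModel | None = None,
    iters: int = 100_000,
    burn_in: int = 10_000,
    n_starts: int = 3,
    seed: int = 0,
    proposal: str = "transposition",
) -> SubtypeModel:
    """Fit a C-subtype event-ordering mixture by Metropolis MCMC ascent.

    Each iteration proposes a symmetric swap of two event positions within a
    uniformly chosen subtype's ordering (``proposal='adjacent'`` restricts to
    neighbouring positions) and accepts by the Metropolis rule on the mixture
    log-likelihood; fractions are refreshed every sweep (N iterations) from
    responsibility means.  The maximum-likelihood state visited across all
    restarts is returned, with acceptance-rate diagnostics computed after
    burn-in.  Deterministic given ``seed``.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if iters <= burn_in:
        raise ValueError("iters must exceed burn_in")
    if proposal not in ("transposition", "adjacent"):
        raise ValueError(f"unknown proposal kernel {proposal!r}")
    noise = noise or NoiseModel()
    values = matrix.values
    if values.sum() == 0:
        raise ValueError("all-zero matrix carries no ordering information")
    event_names = matrix.event_names
    n, N = values.shape
    l_occ, l_not = _log_bernoulli_terms(values, noise)
    rng = np.random.default_rng(seed)

    best_ll = -np.inf
    best_perms: list[np.ndarray] | None = None
    best_fracs: np.ndarray | None = None
    accept_counts = []
    for start in range(n_starts):
        perms, fracs = _init_orderings(values, event_names, C, rng, start)
        per_subtype = np.stack([_subtype_loglik(l_occ, l_not, p) for p in perms], axis=1)
        current_ll = _mixture_loglik(per_subtype, fracs)
        if current_ll > best_ll:
            best_ll, best_perms, best_fracs = current_ll, [p.copy() for p in perms], fracs.copy()
        accepted = 0
        proposed_post_burnin = 0
        for it in range(iters):
            c = int(rng.integers(0, C))
            if proposal == "adjacent":
                i = int(rng.integers(0, N - 1))
                j = i + 1
            else:
                i, j = rng.integers(0, N, size=2)
                if i == j:
                    continue
            cand = perms[c].copy()
            cand[i], cand[j] = cand[j], cand[i]
            cand_col = _subtype_loglik(l_occ, l_not, cand)
            new_per = per_subtype.copy()
            new_per[:, c] = cand_col
            new_ll = _mixture_loglik(new_per, fracs)
            if it >= burn_in:
                proposed_post_burnin += 1
            if new_ll >= current_ll or rng.random() < np.exp(new_ll - current_ll):
                perms[c] = cand
                per_subtype = new_per
                current_ll = new_ll
                if it >= burn_in:
                    accepted += 1
                if current_ll > best_ll:
                    best_ll = current_ll
                    best_perms = [p.copy() for p in perms]
                    best_fracs = fracs.copy()
            if (it + 1) % N == 0 and C > 1:
                fracs = _responsibility_fractions(per_subtype, fracs)
                current_ll = _mixture_loglik(per_subtype, fracs)
                if current_ll > best_ll:
                    best_ll = current_ll
                    best_perms = [p.copy() for p in perms]
                    best_fracs = fracs.copy()
        accept_counts.append(accepted / max(proposed_post_burnin, 1))

    assert best_perms is not None and best_fracs is not None
    orderings = [EventOrdering([event_names[i] for i in p]) for p in best_perms]
    # canonical subtype order: descending fraction, ties by first event name
    order = sorted(
        range(C), key=lambda c: (-best_fracs[c], orderings[c].events)
    )
    model = SubtypeModel(
        orderings=[orderings[c] for c in order],
        fractions=best_fracs[order] / best_fracs[order].sum(),
        noise=noise,
        log_likelihood=best_ll,
        mcmc_summary={
            "iters": iters,
            "burn_in": burn_in,
            "n_starts": n_starts,
            "proposal": proposal,
            "acceptance_rate_post_burnin": accept_counts,
            "seed": seed,
        },
    )
    return model


def select_subtype_count(
    matrix: BinaryMutationMatrix,
    C_max: int = 5,
    folds: int = 5,
    noise: NoiseModel | None = None,
    iters: int = 2_000,
    burn_in: int = 200,
    n_starts: int = 1,
    seed: int = 0,
) -> CVReport:
    """Choose the number of subtypes by cross-validated held-out likelihood.

    For each C in 1..C_max the model is fitted on the training folds and
    scored by the mean per-sample log-likelihood of the held-out fold.  The
    winner maximises the mean across folds; candidates whose mean lies
    within one standard error of the winner are near-ties, resolved toward
    the smaller C (the conservative model-stability reading).
    """
    n = len(matrix.sample_ids)
    if folds > n:
        raise ValueError("more folds than samples")
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    candidates = list(range(1, C_max + 1))
    fold_ll: dict[int, list[float]] = {c: [] for c in candidates}
    idx = np.arange(n)
    for f, (train, test) in enumerate(kf.split(idx)):
        train_m = BinaryMutationMatrix(matrix.data.iloc[train].copy())
        test_m = BinaryMutationMatrix(matrix.data.iloc[test].copy())
        for C in candidates:
            model = fit_model(
                train_m, C, noise, iters=iters, burn_in=burn_in,
                n_starts=n_starts, seed=seed + 1000 * f + C,
            )
            per_sample, _ = data_log_likelihood(test_m, model)
            fold_ll[C].append(float(per_sample.mean()))
    mean = {c: float(np.mean(fold_ll[c])) for c in candidates}
    se = {
        c: float(np.std(fold_ll[c], ddof=1) / np.sqrt(folds)) if folds > 1 else 0.0
        for c in candidates
    }
    best = max(candidates, key=lambda c: mean[c])
    chosen = min(c for c in candidates if mean[c] >= mean[best] - se[best])
    return CVReport(candidates, fold_ll, mean, se, chosen)


def assign_subjects(
    matrix: BinaryMutationMatrix, model: SubtypeModel
) -> AssignmentTable:
    """Posterior subtype responsibilities and stage posteriors per sample.

    Responsibilities are proportional to f_c P(x|S_c); the stage posterior
    is computed within the MAP subtype.  Argmax ties break toward the lower
    subtype index / earlier stage.
    """
    _check_events(matrix, model)
    l_occ, l_not = _log_bernoulli_terms(matrix.values, model.noise)
    perms = _perms_for_model(matrix, model)
    per_subtype = np.stack([_subtype_loglik(l_occ, l_not, p) for p in perms], axis=1)
    with np.errstate(divide="ignore"):
        log_w = per_subtype + np.log(model.fractions)[None, :]
    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    resp = np.exp(log_w)
    map_subtype = resp.argmax(axis=1)

    n = len(matrix.sample_ids)
    stage_post = np.empty((n, len(model.event_names) + 1))
    for c in range(model.n_subtypes):
        mask = map_subtype == c
        if mask.any():
            s = _stage_loglik(l_occ[mask], l_not[mask], perms[c])
            s -= logsumexp(s, axis=1, keepdims=True)
            stage_post[mask] = np.exp(s)
    map_stage = stage_post.argmax(axis=1)
    return AssignmentTable(
        sample_ids=matrix.sample_ids,
        responsibilities=resp,
        stage_posteriors=stage_post,
        map_subtype=map_subtype,
        map_stage=map_stage,
    )
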