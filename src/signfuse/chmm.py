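"""Two-chain coupled hidden Markov model with decision-fusion scoring.

Two Markov chains (a gesture chain and a movement-trajectory chain) run
in parallel.  The model's state at time ``t`` is the composite pair
``(q^1_t, q^2_t)``; each chain's next state depends on *both* chains'
previous states, and each chain emits its own observation stream through
a diagonal-Gaussian density, so the joint emission factorizes per chain.

Conventions
-----------
Chain states are 0-based here.  The composite index of ``(i1, i2)`` is
``i1 * N2 + i2`` (chain 2 fastest), used consistently by the transition
matrix, lattices and score vectors.  All inference runs in the log
domain.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

VAR_FLOOR = 1e-6
_ROW_SUM_TOL = 1e-9


@dataclass
class EmissionModel:
    """Diagonal Gaussians, one per chain state: means/vars[c] is (Nc, dc)."""

    means: list[np.ndarray]
    vars: list[np.ndarray]

    def log_density(self, chain: int, obs: np.ndarray) -> np.ndarray:
        """(T, Nc) log density of each frame under each state of a chain."""
        mu = self.means[chain]          # (Nc, d)
        var = self.vars[chain]          # (Nc, d)
        diff = obs[:, None, :] - mu[None, :, :]
        return -0.5 * (
            (diff**2 / var[None, :, :]).sum(axis=2)
            + np.log(2 * np.pi * var).sum(axis=1)[None, :]
        )


@dataclass
class CoupledHMM:
    n1: int
    n2: int
    initial: list[np.ndarray]      # [pi1 (N1,), pi2 (N2,)]
    transitions: list[np.ndarray]  # [A1 (N1,N2,N1), A2 (N1,N2,N2)]
    emissions: EmissionModel

    @property
    def n_composite(self) -> int:
        return self.n1 * self.n2


@dataclass
class TrainReport:
    loglik_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    final_tol: float = float("inf")


def validate_model(m: CoupledHMM) -> list[str]:
    """Empty list iff all structural invariants hold."""
    v: list[str] = []
    for c, (n, pi) in enumerate(zip((m.n1, m.n2), m.initial), start=1):
        if pi.shape != (n,):
            v.append(f"chain {c}: initial vector shape {pi.shape} != ({n},)")
            continue
        if (pi < 0).any():
            v.append(f"chain {c}: negative initial probability")
        if abs(pi.sum() - 1.0) > _ROW_SUM_TOL:
            v.append(f"chain {c}: initial vector sums to {pi.sum()!r}")
    for c, (nc, A) in enumerate(zip((m.n1, m.n2), m.transitions), start=1):
        if A.shape != (m.n1, m.n2, nc):
            v.append(f"chain {c}: transition tensor shape {A.shape}")
            continue
        if (A < 0).any():
            v.append(f"chain {c}: negative transition probability")
        sums = A.sum(axis=2)
        bad = np.argwhere(np.abs(sums - 1.0) > _ROW_SUM_TOL)
        for i1, i2 in bad:
            v.append(
                f"chain {c}: row for composite ({i1},{i2}) sums to {sums[i1, i2]!r}"
            )
    for c in (0, 1):
        if (m.emissions.vars[c] < VAR_FLOOR).any():
            v.append(f"chain {c + 1}: emission variance below floor {VAR_FLOOR}")
        if m.emissions.means[c].shape != m.emissions.vars[c].shape:
            v.append(f"chain {c + 1}: emission mean/var shape mismatch")
    return v


def composite_transition_matrix(m: CoupledHMM) -> np.ndarray:
    """(N1*N2, N1*N2) matrix; entry [(i1,i2),(j1,j2)] = A1[i1,i2,j1]*A2[i1,i2,j2]."""
    problems = validate_model(m)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    A1, A2 = m.transitions
    joint = A1[:, :, :, None] * A2[:, :, None, :]  # (N1,N2,N1,N2)
    return joint.reshape(m.n_composite, m.n_composite)


def _composite_log_quantities(m: CoupledHMM, obs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log pi (S,), log M (S,S), log b (T,S)) on the composite lattice."""
    o1, o2 = np.asarray(obs.gesture, float), np.asarray(obs.trajectory, float)
    if o1.shape[1] != m.emissions.means[0].shape[1]:
        raise ValueError(
            f"gesture stream dim {o1.shape[1]} != emission dim "
            f"{m.emissions.means[0].shape[1]}"
        )
    if o2.shape[1] != m.emissions.means[1].shape[1]:
        raise ValueError(
            f"trajectory stream dim {o2.shape[1]} != emission dim "
            f"{m.emissions.means[1].shape[1]}"
        )
    with np.errstate(divide="ignore"):
        log_pi = (
            np.log(m.initial[0])[:, None] + np.log(m.initial[1])[None, :]
        ).ravel()
        A1, A2 = m.transitions
        log_M = np.log(
            (A1[:, :, :, None] * A2[:, :, None, :]).reshape(
                m.n_composite, m.n_composite
            )
        )
    lb1 = m.emissions.log_density(0, o1)  # (T, N1)
    lb2 = m.emissions.log_density(1, o2)  # (T, N2)
    log_b = (lb1[:, :, None] + lb2[:, None, :]).reshape(len(o1), m.n_composite)
    return log_pi, log_M, log_b


def log_forward(m: CoupledHMM, obs) -> tuple[float, np.ndarray]:
    """Exact forward recursion; returns (log P(O|model), lattice (T, S))."""
    log_pi, log_M, log_b = _composite_log_quantities(m, obs)
    T = log_b.shape[0]
    alpha = np.empty((T, m.n_composite))
    alpha[0] = log_pi + log_b[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + log_M, axis=0) + log_b[t]
    return float(logsumexp(alpha[-1])), alpha


def log_backward(m: CoupledHMM, obs) -> np.ndarray:
    """(T, S) backward lattice."""
    _log_pi, log_M, log_b = _composite_log_quantities(m, obs)
    T = log_b.shape[0]
    beta = np.empty((T, m.n_composite))
    beta[-1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_M + (log_b[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def brute_force_loglik(m: CoupledHMM, obs, max_paths: int = 10**6) -> float:
    """Path-enumeration likelihood (testing oracle for :func:`log_forward`)."""
    log_pi, log_M, log_b = _composite_log_quantities(m, obs)
    T = log_b.shape[0]
    S = m.n_composite
    if S**T > max_paths:
        raise ValueError(f"state space {S}^{T} exceeds {max_paths} paths")
    terms = []
    for path in itertools.product(range(S), repeat=T):
        lp = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_M[path[t - 1], path[t]] + log_b[t, path[t]]
        terms.append(lp)
    return float(logsumexp(terms))


def sample_sequence(m: CoupledHMM, T_obs: int, seed: int):
    """Draw a composite state path and observations; returns (path, ObservationPair)."""
    from .features import ObservationPair

    if T_obs < 1:
        raise ValueError("T_obs must be >= 1")
    rng = np.random.default_rng(seed)
    A1, A2 = m.transitions
    i1 = rng.choice(m.n1, p=m.initial[0])
    i2 = rng.choice(m.n2, p=m.initial[1])
    path = [(int(i1), int(i2))]
    for _ in range(T_obs - 1):
        j1 = rng.choice(m.n1, p=A1[i1, i2])
        j2 = rng.choice(m.n2, p=A2[i1, i2])
        i1, i2 = j1, j2
        path.append((int(i1), int(i2)))
    d1 = m.emissions.means[0].shape[1]
    d2 = m.emissions.means[1].shape[1]
    o1 = np.empty((T_obs, d1))
    o2 = np.empty((T_obs, d2))
    for t, (s1, s2) in enumerate(path):
        o1[t] = rng.normal(m.emissions.means[0][s1], np.sqrt(m.emissions.vars[0][s1]))
        o2[t] = rng.normal(m.emissions.means[1][s2], np.sqrt(m.emissions.vars[1][s2]))
    return path, ObservationPair(gesture=o1, trajectory=o2)


def em_fit(
    init: CoupledHMM,
    dataset: list,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[CoupledHMM, TrainReport]:
    """Baum-Welch on the composite lattice with factorized M-steps.

    E-step: forward-backward posteriors over composite states.  M-step:
    per-chain initial vectors from the chain marginals of the first-frame
    posterior; each chain's coupled transition tensor from the pairwise
    posteriors summed over the *other* chain's next state; Gaussian
    means/variances from per-chain marginal posteriors.  The total
    log-likelihood is non-decreasing (up to 1e-8 slack).
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    problems = validate_model(init)
    if problems:
        raise ValueError("invalid initial model: " + "; ".join(problems))
    m = CoupledHMM(
        n1=init.n1,
        n2=init.n2,
        initial=[p.copy() for p in init.initial],
        transitions=[A.copy() for A in init.transitions],
        emissions=EmissionModel(
            means=[mu.copy() for mu in init.emissions.means],
            vars=[v.copy() for v in init.emissions.vars],
        ),
    )
    N1, N2, S = m.n1, m.n2, m.n_composite
    report = TrainReport()
    prev_ll = -np.inf
    for it in range(max_iter):
        log_pi_c = [None, None]
        init_counts = [np.zeros(N1), np.zeros(N2)]
        xi_sum = np.zeros((S, S))
        w_sum = [np.zeros(N1), np.zeros(N2)]
        wx_sum = [
            np.zeros_like(m.emissions.means[0]),
            np.zeros_like(m.emissions.means[1]),
        ]
        wx2_sum = [
            np.zeros_like(m.emissions.means[0]),
            np.zeros_like(m.emissions.means[1]),
        ]
        total_ll = 0.0
        for obs in dataset:
            _lp, log_M, log_b = _composite_log_quantities(m, obs)
            ll, alpha = log_forward(m, obs)
            beta = log_backward(m, obs)
            total_ll += ll
            gamma = np.exp(alpha + beta - ll)          # (T, S)
            T_obs = gamma.shape[0]
            g0 = gamma[0].reshape(N1, N2)
            init_counts[0] += g0.sum(axis=1)
            init_counts[1] += g0.sum(axis=0)
            for t in range(T_obs - 1):
                xi_sum += np.exp(
                    alpha[t][:, None]
                    + log_M
                    + (log_b[t + 1] + beta[t + 1])[None, :]
                    - ll
                )
            g = gamma.reshape(T_obs, N1, N2)
            w1 = g.sum(axis=2)  # (T, N1)
            w2 = g.sum(axis=1)  # (T, N2)
            for c, (w, o) in enumerate(
                ((w1, np.asarray(obs.gesture, float)), (w2, np.asarray(obs.trajectory, float)))
            ):
                w_sum[c] += w.sum(axis=0)
                wx_sum[c] += w.T @ o
                wx2_sum[c] += w.T @ (o**2)
        report.loglik_trace.append(total_ll)
        report.iterations = it + 1
        rel = abs(total_ll - prev_ll) / (abs(prev_ll) + 1e-12)
        report.final_tol = rel
        if total_ll < prev_ll - 1e-8:
            warnings.warn(
                f"log-likelihood decreased at iteration {it}: "
                f"{prev_ll} -> {total_ll}"
            )
        if np.isfinite(prev_ll) and rel < tol:
            report.converged = True
            break
        prev_ll = total_ll

        # ---- M-step ----
        for c in (0, 1):
            tot = init_counts[c].sum()
            if tot > 0:
                m.initial[c] = init_counts[c] / tot
        xi4 = xi_sum.reshape(N1, N2, N1, N2)
        for c, axis in ((0, 3), (1, 2)):
            counts = xi4.sum(axis=axis)  # (N1, N2, Nc)
            row_tot = counts.sum(axis=2)
            new_A = m.transitions[c].copy()
            nz = row_tot > 0
            new_A[nz] = counts[nz] / row_tot[nz][:, None]
            m.transitions[c] = new_A
        floored = False
        for c in (0, 1):
            seen = w_sum[c] > 1e-12
            mu = m.emissions.means[c].copy()
            var = m.emissions.vars[c].copy()
            mu[seen] = wx_sum[c][seen] / w_sum[c][seen, None]
            var[seen] = (
                wx2_sum[c][seen] / w_sum[c][seen, None] - mu[seen] ** 2
            )
            if (var[seen] < VAR_FLOOR).any():
                floored = True
            var = np.maximum(var, VAR_FLOOR)
            m.emissions.means[c] = mu
            m.emissions.vars[c] = var
        if floored:
            warnings.warn("emission variance floored at VAR_FLOOR")
    return m, report


def state_scores(m: CoupledHMM, obs) -> np.ndarray:
    """Length-normalized log-likelihood of dwelling in each composite state.

    ``score[(i1,i2)] = [log pi + (T-1) log a_self + sum_t log b] / T`` with
    the initial, self-transition and emission terms all taken as the
    per-chain products.  Returns an (N1*N2,) vector in composite order;
    a zero-probability self-transition yields ``-inf``.
    """
    o1, o2 = np.asarray(obs.gesture, float), np.asarray(obs.trajectory, float)
    T_obs = len(o1)
    lb1 = m.emissions.log_density(0, o1).sum(axis=0)  # (N1,)
    lb2 = m.emissions.log_density(1, o2).sum(axis=0)  # (N2,)
    A1, A2 = m.transitions
    i1 = np.arange(m.n1)
    i2 = np.arange(m.n2)
    with np.errstate(divide="ignore"):
        self1 = np.log(A1[i1[:, None], i2[None, :], i1[:, None]])  # (N1,N2)
        self2 = np.log(A2[i1[:, None], i2[None, :], i2[None, :]])
        lpi = np.log(m.initial[0])[:, None] + np.log(m.initial[1])[None, :]
    scores = (
        lpi
        + (T_obs - 1) * (self1 + self2)
        + lb1[:, None]
        + lb2[None, :]
    ) / T_obs
    return scores.ravel()


def classify_word(
    m: CoupledHMM,
    stage_obs: list,
    lex,
    category: str | None = None,
):
    """Pick the lexicon word best explaining per-stage observations.

    Candidates are entries with the same stage count (and category, if
    given — recognition uses one status table per vocabulary category).
    A word's score is the sum over stages of the dwell score of its
    stage's composite state; ties break toward the smaller word_id.
    Returns ``(word_id, candidates)`` with candidates sorted best-first
    as ``(word_id, total_score, per_stage_scores)``.
    """
    if not stage_obs:
        raise ValueError("stage_obs must be non-empty")
    per_stage = [state_scores(m, obs) for obs in stage_obs]
    candidates = []
    for e in lex.entries:
        if len(e.stages) != len(stage_obs):
            continue
        if category is not None and e.category != category:
            continue
        stage_scores = [
            per_stage[k][(s.gesture - 1) * m.n2 + s.movement]
            for k, s in enumerate(e.stages)
        ]
        candidates.append((e.word_id, float(sum(stage_scores)), stage_scores))
    if not candidates:
        raise LookupError(
            f"no lexicon candidate with {len(stage_obs)} stages"
            + (f" in category {category}" if category else "")
        )
    candidates.sort(key=lambda c: (-c[1], c[0]))
    return candidates[0][0], candidates


# ---------------------------------------------------------------------------
# Model serialization (JSON, round-trip exact)
# ---------------------------------------------------------------------------

def model_to_dict(m: CoupledHMM) -> dict:
    return {
        "N1": m.n1,
        "N2": m.n2,
        "initial": [p.tolist() for p in m.initial],
        "coupled_transitions": [A.tolist() for A in m.transitions],
        "emissions": {
            "means": [mu.tolist() for mu in m.emissions.means],
            "vars": [v.tolist() for v in m.emissions.vars],
        },
    }


def model_from_dict(d: dict) -> CoupledHMM:
    return CoupledHMM(
        n1=int(d["N1"]),
        n2=int(d["N2"]),
        initial=[np.asarray(p, float) for p in d["initial"]],
        transitions=[np.asarray(A, float) for A in d["coupled_transitions"]],
        emissions=EmissionModel(
            means=[np.asarray(mu, float) for mu in d["emissions"]["means"]],
            vars=[np.asarray(v, float) for v in d["emissions"]["vars"]],
        ),
    )


def save_model(m: CoupledHMM, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(m)), encoding="utf-8")


def load_model(path: str | Path) -> CoupledHMM:
    return model_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
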