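"""Synthetic cohort generator.

Emulates the statistical structure the connectivity pipeline assumes: each
subject-session's 14 component time courses are drawn from a small set of
recurring covariance "states" visited by a sticky Markov chain at TR
resolution, the post-treatment session carries planted connectivity changes
(one pair increased, one decreased), and per-subject cognitive change scores
are linearly coupled to baseline connectivity features plus Gaussian noise.

Every ``simulate_*`` operation is deterministic given its seed; the cohort
seed fans out to per-subject substreams (``numpy.random.SeedSequence``), so
adding a subject does not perturb the others.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    NETWORK_LABELS,
    FourDDataset,
    TimeCourses,
    TimeCourseSet,
    matrix_to_pairs,
)
from .errors import ArgumentError, ConfigError

_STRUCTURE_SEED = 20230  # fixed: state geometry is part of the study design, not a random draw

Pair = tuple[int, int]


def _sign_patterns(
    n_states: int, n_components: int, rng: np.random.Generator, n_fixed: int = 4
) -> np.ndarray:
    """±1 vectors with pairwise Hamming distance near half the free length.

    Two states whose sign vectors differ in h positions disagree (in the sign
    of the planted correlation) on h*(n-h) component pairs, which is what
    makes the default states well separated in pair-vector space.  The first
    ``n_fixed`` components keep a fixed positive sign in every state, so
    connectivity among them is state-invariant: those pairs carry purely
    subject-level information, which is what the planted
    prediction couplings need.
    """
    n_free = n_components - min(n_fixed, n_components)
    lo, hi = max(1, n_free // 3), n_free - n_free // 3
    patterns = [np.ones(n_components)]
    attempts = 0
    while len(patterns) < n_states:
        cand = np.ones(n_components)
        cand[n_components - n_free :] = rng.choice([-1.0, 1.0], size=n_free)
        if all(lo <= int(np.sum(cand != p)) <= hi for p in patterns):
            patterns.append(cand)
        attempts += 1
        if attempts > 10_000:  # pragma: no cover - only for extreme configs
            raise ConfigError(
                f"could not place {n_states} separated states over {n_components} components"
            )
    return np.stack(patterns)


def default_state_correlations(
    n_states: int = 5, n_components: int = 14, strength: float = 0.6
) -> list[np.ndarray]:
    """Default planted state correlation matrices.

    State s has R_ij = strength * v_i * v_j for a state-specific sign vector
    v (rank-one plus diagonal), i.e. every pair is correlated at ±strength
    and states differ by the sign pattern.  All matrices are positive
    definite (smallest eigenvalue 1 - strength).
    """
    if not 0 < strength < 1:
        raise ConfigError("strength must be in (0, 1)")
    rng = np.random.default_rng(_STRUCTURE_SEED)
    patterns = _sign_patterns(n_states, n_components, rng)
    mats = []
    for v in patterns:
        r = strength * np.outer(v, v)
        np.fill_diagonal(r, 1.0)
        mats.append(r)
    return mats


def _check_spd(mat: np.ndarray, what: str) -> None:
    if not np.allclose(mat, mat.T):
        raise ConfigError(f"{what} is not symmetric")
    if np.linalg.eigvalsh(mat)[0] <= 0:
        raise ConfigError(f"{what} is not positive definite")


def nearest_correlation(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalues are clipped at ``floor`` and the result rescaled back to a
    unit diagonal.
    """
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated study: 30 treated patients scanned pre and
    post, 14 network components, 230 TRs at TR = 2 s, five recurring
    connectivity states with sticky switching (stay probability 0.99, mean
    dwell 100 TRs so windows are mostly state-pure), a +0.3 correlation
    increase planted on rFPN-lFPN and a
    -0.3 decrease on pVN-mVN in the post session, trait-like per-subject
    connectivity offsets shared across sessions (``subject_sd``), and two
    state-invariant baseline sFNC pairs linearly driving the memory change
    score at a planted signal-to-noise variance ratio of about 2.
    """

    n_subjects: int = 30
    n_components: int = 14
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    n_states: int = 5
    stay_prob: float = 0.99
    state_covariances: list[np.ndarray] | None = None
    treatment_effects: list[tuple[Pair, float]] = field(
        default_factory=lambda: [((0, 1), 0.3), ((4, 5), -0.3)]
    )
    prediction_couplings: list[tuple[Pair, float]] = field(
        default_factory=lambda: [((0, 1), 1.0), ((2, 3), 1.0)]
    )
    noise_sd: float = 0.2
    subject_sd: float = 0.15
    cognition_noise_sd: float = 0.16
    state_strength: float = 0.6
    seed: int = 0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_components < 2 or self.n_timepoints < 1:
            raise ConfigError("n_subjects, n_components, n_timepoints must be positive")
        if self.n_states < 1:
            raise ConfigError("n_states must be >= 1")
        if not 0.0 < self.stay_prob < 1.0:
            if not (self.stay_prob == 1.0 and self.n_states == 1):
                raise ConfigError("stay_prob must lie in (0, 1)")
        if self.noise_sd < 0 or self.cognition_noise_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        if self.labels is None:
            if self.n_components == len(NETWORK_LABELS):
                self.labels = NETWORK_LABELS
            else:
                self.labels = tuple(f"IC{i + 1:02d}" for i in range(self.n_components))
        if self.state_covariances is None:
            self.state_covariances = default_state_correlations(
                self.n_states, self.n_components, self.state_strength
            )
        if len(self.state_covariances) != self.n_states:
            raise ConfigError("need one covariance matrix per state")
        for s, cov in enumerate(self.state_covariances):
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.n_components, self.n_components):
                raise ConfigError(f"state {s} covariance has wrong shape {cov.shape}")
            _check_spd(cov, f"state {s} covariance")
            self.state_covariances[s] = cov
        for (i, j), _ in self.treatment_effects + self.prediction_couplings:
            if not (0 <= i < self.n_components and 0 <= j < self.n_components and i != j):
                raise ConfigError(f"pair ({i}, {j}) does not index distinct components")

    def pair_name(self, pair: Pair) -> str:
        i, j = sorted(pair)
        return f"{self.labels[i]}-{self.labels[j]}"

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["state_covariances"] = [c.tolist() for c in self.state_covariances]
        d["labels"] = list(self.labels)
        d["treatment_effects"] = [[list(p), float(b)] for p, b in self.treatment_effects]
        d["prediction_couplings"] = [[list(p), float(b)] for p, b in self.prediction_couplings]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if d.get("state_covariances") is not None:
            d["state_covariances"] = [np.asarray(c) for c in d["state_covariances"]]
        if d.get("labels") is not None:
            d["labels"] = tuple(d["labels"])
        for key in ("treatment_effects", "prediction_couplings"):
            if d.get(key):
                d[key] = [(tuple(p), float(b)) for p, b in d[key]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted quantities for evaluating downstream recovery."""

    state_sequences: dict[tuple[str, str], np.ndarray]
    true_centroids: np.ndarray  # (n_states, n_pairs), Fisher-z of planted correlations
    planted_betas: dict[str, float] = field(default_factory=dict)
    true_deltas: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_sequences": {
                f"{sub}/{ses}": seq.tolist() for (sub, ses), seq in self.state_sequences.items()
            },
            "true_centroids": self.true_centroids.tolist(),
            "planted_betas": self.planted_betas,
            "true_deltas": None if self.true_deltas is None else self.true_deltas.tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


def simulate_state_sequence(
    n_steps: int,
    n_states: int,
    stay_prob: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample a sticky Markov chain over states.

    The chain stays in place with probability ``stay_prob`` and otherwise
    jumps uniformly to one of the other states; the initial state is uniform.
    Its stationary distribution is uniform over states.
    """
    if n_steps < 1:
        raise ArgumentError("n_steps must be >= 1")
    if n_states < 1:
        raise ArgumentError("n_states must be >= 1")
    if not 0.0 < stay_prob <= 1.0:
        raise ArgumentError("stay_prob must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = np.empty(n_steps, dtype=np.int64)
    seq[0] = rng.integers(n_states)
    if n_states == 1:
        seq[:] = 0
        return seq
    stay = rng.random(n_steps - 1) < stay_prob
    jumps = rng.integers(n_states - 1, size=n_steps - 1)
    for t in range(1, n_steps):
        if stay[t - 1]:
            seq[t] = seq[t - 1]
        else:
            j = jumps[t - 1]
            seq[t] = j if j < seq[t - 1] else j + 1  # uniform over the other states
    return seq


def _post_correlations(config: CohortConfig) -> list[np.ndarray]:
    """Apply treatment effects (correlation scale) to every state's matrix."""
    mats = []
    for s, pre in enumerate(config.state_covariances):
        post = pre.copy()
        for (i, j), delta in config.treatment_effects:
            new_r = post[i, j] + delta
            if abs(new_r) >= 1.0:
                raise ConfigError(
                    f"treatment effect on pair {config.pair_name((i, j))} drives state {s} "
                    f"correlation to {new_r:+.3f} (outside (-1, 1))"
                )
            post[i, j] = post[j, i] = new_r
        post = nearest_correlation(post)
        if np.linalg.eigvalsh(post)[0] <= 0:  # pragma: no cover - nearest_correlation guards
            raise ConfigError(
                "post-session covariance not positive definite after treatment effects on "
                + ", ".join(config.pair_name(p) for p, _ in config.treatment_effects)
            )
        mats.append(post)
    return mats


def simulate_timecourses(config: CohortConfig) -> tuple[TimeCourseSet, GroundTruth]:
    """Draw per-subject pre/post component time courses from the planted states.

    Each TR's component vector is sampled from the covariance of the chain's
    current state (post-session matrices carry the treatment effects), plus
    isotropic observation noise of scale ``config.noise_sd``.
    """
    pre_cov = config.state_covariances
    post_cov = _post_correlations(config)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_subjects)
    items: list[TimeCourses] = []
    sequences: dict[tuple[str, str], np.ndarray] = {}
    T, C = config.n_timepoints, config.n_components
    for s_idx, ss in enumerate(streams):
        subject = f"{s_idx + 1:03d}"
        sub_rng = np.random.default_rng(ss)
        # trait-like connectivity offsets: shared by both sessions and all
        # states, so baseline FNC carries subject-specific information
        offset = np.zeros((C, C))
        if config.subject_sd > 0:
            tri = np.triu_indices(C, k=1)
            vals = config.subject_sd * sub_rng.standard_normal(len(tri[0]))
            offset[tri] = vals
            offset += offset.T
        chol = {
            ses: [
                np.linalg.cholesky(nearest_correlation(c + offset))
                for c in (pre_cov if ses == "pre" else post_cov)
            ]
            for ses in ("pre", "post")
        }
        for session in ("pre", "post"):
            seq = simulate_state_sequence(T, config.n_states, config.stay_prob, sub_rng)
            z = sub_rng.standard_normal((T, C))
            x = np.empty((T, C))
            for state in range(config.n_states):
                m = seq == state
                if m.any():
                    x[m] = z[m] @ chol[session][state].T
            if config.noise_sd > 0:
                x += config.noise_sd * sub_rng.standard_normal((T, C))
            items.append(
                TimeCourses(
                    subject=subject,
                    session=session,
                    data=x.T,
                    tr_seconds=config.tr_seconds,
                    labels=config.labels,
                )
            )
            sequences[(subject, session)] = seq
    cap = 1.0 - 1e-7
    centroids = np.stack(
        [np.arctanh(np.clip(matrix_to_pairs(c), -cap, cap)) for c in pre_cov]
    )
    truth = GroundTruth(state_sequences=sequences, true_centroids=centroids)
    return TimeCourseSet(items), truth


def simulate_cognition(
    config: CohortConfig,
    baseline_features: pd.DataFrame,
    seed: int | None = None,
    noise_sd: float | None = None,
    domain: str = "memory",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate pre/post cognitive scores coupled to baseline connectivity.

    ``baseline_features`` is a subjects x named-features frame (e.g. the
    baseline sFNC pair vectors).  The change score is
    ``delta = sum_k beta_k * feature_k + N(0, noise_sd)``; pre scores are
    independent standard normals and post = pre + delta.
    """
    if len(baseline_features) != config.n_subjects:
        raise ArgumentError(
            f"baseline_features has {len(baseline_features)} rows, expected {config.n_subjects}"
        )
    noise = config.cognition_noise_sd if noise_sd is None else float(noise_sd)
    betas: dict[str, float] = {}
    for pair, beta in config.prediction_couplings:
        name = config.pair_name(pair)
        if name not in baseline_features.columns:
            raise ConfigError(f"coupling references unknown feature {name!r}")
        betas[name] = betas.get(name, 0.0) + float(beta)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_subjects
    signal = np.zeros(n)
    for name, beta in betas.items():
        signal += beta * baseline_features[name].to_numpy()
    delta = signal + noise * rng.standard_normal(n)
    pre = rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "subject": list(baseline_features.index),
            f"{domain}_pre": pre,
            f"{domain}_post": pre + delta,
            f"{domain}_delta": delta,
        }
    ).set_index("subject")
    truth = GroundTruth(
        state_sequences={},
        true_centroids=np.empty((0, 0)),
        planted_betas=betas,
        true_deltas=signal,
    )
    return table, truth


def laplacian_maps(
    n_components: int, n_voxels: int, seed: int = 7, scale: float = 1.0
) -> np.ndarray:
    """Random super-Gaussian spatial maps (one per component).

    Laplacian-distributed voxel loadings give the sparse, heavy-tailed
    spatial structure that spatial ICA relies on to separate components.
    """
    rng = np.random.default_rng(seed)
    return rng.laplace(scale=scale, size=(n_components, n_voxels))


def simulate_voxel_dataset(
    maps: np.ndarray,
    timecourses: TimeCourseSet,
    noise_sd: float,
    seed: int,
) -> FourDDataset:
    """Mix spatial maps by each subject-session's time courses plus noise.

    Returns one voxel x time matrix per subject-session entry of
    ``timecourses`` (``data = maps.T @ tcs + noise``) on an all-true mask.
    """
    maps = np.asarray(maps, dtype=float)
    first = next(iter(timecourses))
    if maps.shape[0] != first.n_components:
        raise ConfigError(
            f"{maps.shape[0]} maps but {first.n_components} components in the time courses"
        )
    if np.linalg.matrix_rank(maps) < maps.shape[0]:
        raise ConfigError("spatial maps are rank deficient (linearly dependent)")
    rng = np.random.default_rng(seed)
    data, ids = [], []
    for tc in timecourses:
        x = maps.T @ tc.data
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal(x.shape)
        data.append(x)
        ids.append(f"{tc.subject}_{tc.session}")
    mask = np.ones(maps.shape[1], dtype=bool)
    return FourDDataset(data=data, subject_ids=ids, mask=mask)
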