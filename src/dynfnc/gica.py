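"""Group spatial ICA: order selection, two-stage PCA, Infomax, ICASSO,
spatial-temporal back-reconstruction, and template-based network labelling.

Multi-subject voxel x time data are reduced per subject by temporal PCA,
concatenated along the reduced time dimension, reduced again at the group
level, and unmixed by Infomax ICA into spatially independent group maps.
Subject-specific time courses and maps are recovered by two regression
passes against the group maps (spatial then temporal regression).  The
model order can be estimated from the eigenvalue spectrum by the classical
minimum-description-length criterion, and component reliability is
assessed by re-running ICA with different seeds and clustering the pooled
estimates (ICASSO).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ComponentSet, FourDDataset, TimeCourses, TimeCourseSet
from .errors import ArgumentError, DegenerateDataError, RankDeficiencyError


@dataclass
class GicaConfig:
    """Decomposition parameters.

    Defaults follow the emulated study protocol: 51 principal components at
    the reduction stage, 34 independent components, 20 stability runs.
    """

    n_pc: int = 51
    n_ic: int = 34
    n_runs: int = 20
    seed: int = 0
    max_iter: int = 2048
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_ic > self.n_pc:
            raise ArgumentError(f"n_ic={self.n_ic} exceeds n_pc={self.n_pc}")


def estimate_order_mdl(data: np.ndarray) -> int:
    """Model order from the eigenvalue spectrum (classical MDL).

    ``data`` is voxels x time; voxels are treated as i.i.d. samples of a
    time-dimensional vector.  For each candidate order q the criterion is

        MDL(q) = -N (p - q) log(gm_q / am_q) + 0.5 q (2p - q + 1) log N

    where gm_q and am_q are the geometric and arithmetic means of the
    p - q smallest covariance eigenvalues and N is the voxel count.  The
    minimizing q is returned.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ArgumentError("data must be 2-D with time dimension >= 3")
    if np.allclose(X, X.flat[0]):
        raise DegenerateDataError("data are constant")
    N, p = X.shape
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / N
    evals = np.linalg.eigvalsh(cov)[::-1]
    evals = np.clip(evals, 1e-300, None)
    mdl = np.empty(p - 1)
    log_evals = np.log(evals)
    for q in range(p - 1):
        tail = evals[q:]
        gm = log_evals[q:].mean()
        am = np.log(tail.mean())
        mdl[q] = -N * (p - q) * (gm - am) + 0.5 * q * (2 * p - q + 1) * np.log(N)
    return int(np.argmin(mdl))


@dataclass
class ReducedData:
    """Two-stage PCA output plus the operators needed to trace it back."""

    group: np.ndarray  # (n_voxels, n_ic)
    subject_operators: dict[str, np.ndarray]  # time x n_pc per subject
    group_operator: np.ndarray  # (n_subjects * n_pc, n_ic)


def two_stage_pca(dataset: FourDDataset, n_pc: int, n_ic: int) -> ReducedData:
    """Subject-level temporal PCA, concatenation, group-level PCA.

    Each subject's voxel x time matrix is projected onto its top ``n_pc``
    temporal principal directions, the reduced matrices are concatenated
    along the reduced-time axis, and a second PCA takes the concatenation
    down to ``n_ic`` dimensions.
    """
    T = dataset.n_timepoints
    if n_pc > T:
        raise ArgumentError(f"n_pc={n_pc} exceeds the time length {T}")
    if n_ic > n_pc:
        raise ArgumentError(f"n_ic={n_ic} exceeds n_pc={n_pc}")
    reduced = []
    operators: dict[str, np.ndarray] = {}
    for sid, X in zip(dataset.subject_ids, dataset.data):
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc.T @ Xc  # time x time
        w, v = np.linalg.eigh(cov)
        R = v[:, ::-1][:, :n_pc]  # top temporal directions
        operators[sid] = R
        reduced.append(Xc @ R)
    concat = np.concatenate(reduced, axis=1)  # voxels x (M * n_pc)
    cov_g = concat.T @ concat
    w, v = np.linalg.eigh(cov_g)
    Rg = v[:, ::-1][:, :n_ic]
    return ReducedData(group=concat @ Rg, subject_operators=operators, group_operator=Rg)


def _whiten(X: np.ndarray, n_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA-whiten rows of X (channels x samples), keeping the top ``n_keep``
    principal directions; returns (whitened, sphering)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    w, v = np.linalg.eigh(cov)
    w = np.clip(w[::-1][:n_keep], 1e-12, None)
    v = v[:, ::-1][:, :n_keep]
    sphering = v.T / np.sqrt(w)[:, None]
    return sphering @ Xc, sphering


@dataclass
class IcaResult:
    unmixing: np.ndarray  # applied to the *input* rows
    sources: np.ndarray  # (n_ic, n_samples)
    converged: bool
    n_iter: int


def infomax_ica(
    reduced: np.ndarray,
    n_ic: int,
    seed: int = 0,
    max_iter: int = 2048,
    tol: float = 1e-6,
    learning_rate: float = 0.1,
    anneal: float = 0.97,
) -> IcaResult:
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    ``reduced`` is channels x samples (whitened and reduced to ``n_ic``
    dimensions internally).  Full-batch natural-gradient updates
    dW = lr * (I + (1 - 2 g(WX)) (WX)^T / n) W with the logistic g; the
    learning rate is multiplied by ``anneal`` whenever an update increases
    the gradient norm (and halved on numerical overshoot), so the iteration
    settles.  Converged when the relative update norm drops below ``tol``;
    otherwise a warning is issued and the partial result flagged.
    """
    X = np.asarray(reduced, dtype=float)
    if X.ndim != 2:
        raise ArgumentError("reduced data must be 2-D (channels x samples)")
    if n_ic > X.shape[0]:
        raise ArgumentError(f"n_ic={n_ic} exceeds the reduced dimension {X.shape[0]}")
    Xw, sphering = _whiten(X, n_ic)
    n, samples = Xw.shape
    rng = np.random.default_rng(seed)
    W = np.eye(n) + 0.01 * rng.standard_normal((n, n))
    identity = np.eye(n)
    lr = learning_rate
    converged = False
    it = 0
    prev_grad_norm = np.inf
    for it in range(1, max_iter + 1):
        U = W @ Xw
        with np.errstate(over="ignore"):
            Y = 1.0 / (1.0 + np.exp(-U))
        grad = (identity + (1.0 - 2.0 * Y) @ U.T / samples) @ W
        grad_norm = float(np.linalg.norm(grad))
        if not np.isfinite(grad_norm) or grad_norm > 1e6:
            lr *= 0.5  # numerical overshoot: restart smaller
            W = identity + 0.01 * rng.standard_normal((n, n))
            prev_grad_norm = np.inf
            continue
        if grad_norm > 1.1 * prev_grad_norm:
            lr *= anneal  # oscillating: settle down
        prev_grad_norm = grad_norm
        step = lr * grad
        step_norm = np.linalg.norm(step) / max(np.linalg.norm(W), 1e-30)
        W = W + step
        if step_norm < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Infomax did not converge in {max_iter} iterations "
            f"(last relative update {step_norm:.2e})",
            RuntimeWarning,
        )
    sources = W @ Xw
    return IcaResult(unmixing=W @ sphering, sources=sources, converged=converged, n_iter=it)


def _flip_signs(maps: np.ndarray) -> np.ndarray:
    """Sign convention: each map's largest-|value| voxel is positive."""
    flips = np.sign(maps[np.arange(maps.shape[0]), np.abs(maps).argmax(axis=1)])
    flips[flips == 0] = 1.0
    return maps * flips[:, None]


def icasso_stability(
    reduced: np.ndarray, config: GicaConfig, seeds: list[int] | None = None
) -> ComponentSet:
    """Run Infomax ``n_runs`` times and cluster pooled estimates.

    Pooled component estimates (rows over voxels) are clustered by
    average-linkage agglomeration of the distance 1 - |r| into ``n_ic``
    clusters.  Each cluster's centrotype (the member most similar to the
    rest of its cluster) becomes a group map; its stability index is the
    within-cluster mean |r| minus the between-cluster mean |r|, clipped to
    [0, 1].
    """
    if seeds is None:
        if config.n_runs < 2:
            raise ArgumentError("ICASSO needs n_runs >= 2")
        seeds = [
            int(s) % 2**31
            for s in np.random.SeedSequence(config.seed).generate_state(config.n_runs)
        ]
    elif len(seeds) < 2:
        raise ArgumentError("ICASSO needs n_runs >= 2")
    X = np.asarray(reduced, dtype=float).T  # channels x samples
    pool = []
    converged = True
    for s in seeds:
        res = infomax_ica(
            X, config.n_ic, seed=int(s), max_iter=config.max_iter, tol=config.tol
        )
        converged &= res.converged
        pool.append(res.sources)
    estimates = np.concatenate(pool, axis=0)  # (n_runs * n_ic, samples)
    sim = np.abs(np.corrcoef(estimates))
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(Z, t=config.n_ic, criterion="maxclust")
    maps = np.empty((config.n_ic, estimates.shape[1]))
    stability = np.empty(config.n_ic)
    for idx, c in enumerate(sorted(set(clusters))):
        members = np.flatnonzero(clusters == c)
        others = np.flatnonzero(clusters != c)
        sub = sim[np.ix_(members, members)]
        if members.size == 1:
            within = 1.0
            centrotype = members[0]
        else:
            off = sub[~np.eye(members.size, dtype=bool)]
            within = float(off.mean())
            centrotype = members[int(sub.sum(axis=1).argmax())]
        between = float(sim[np.ix_(members, others)].mean()) if others.size else 0.0
        stability[idx] = float(np.clip(within - between, 0.0, 1.0))
        maps[idx] = estimates[centrotype]
    order = np.argsort(stability)[::-1]
    return ComponentSet(
        group_maps=_flip_signs(maps[order]), stability=stability[order], converged=converged
    )


def back_reconstruct(
    dataset: FourDDataset, group_maps: np.ndarray
) -> tuple[TimeCourseSet, dict[str, np.ndarray]]:
    """Spatial-temporal back-reconstruction of subject time courses and maps.

    Pass 1 (spatial regression): regress each subject's data on the group
    maps across voxels to obtain subject time courses.  Pass 2 (temporal
    regression): regress the data on those time courses across time to
    obtain subject-specific maps.
    """
    G = np.asarray(group_maps, dtype=float)  # (C, V)
    if G.shape[1] != dataset.n_voxels:
        raise ArgumentError("group maps and dataset are on different masks")
    if np.linalg.matrix_rank(G) < G.shape[0]:
        raise RankDeficiencyError("group maps are collinear (rank deficient)")
    labels = tuple(f"IC{i + 1:02d}" for i in range(G.shape[0]))
    items = []
    subject_maps: dict[str, np.ndarray] = {}
    for sid, X in zip(dataset.subject_ids, dataset.data):
        tcs, *_ = np.linalg.lstsq(G.T, X, rcond=None)  # (C, T)
        maps_t, *_ = np.linalg.lstsq(tcs.T, X.T, rcond=None)  # (C, V)
        subject_maps[sid] = maps_t
        if "_" in sid:
            subject, session = sid.rsplit("_", 1)
        else:
            subject, session = sid, "pre"
        items.append(
            TimeCourses(
                subject=subject, session=session, data=tcs, tr_seconds=1.0, labels=labels
            )
        )
    return TimeCourseSet(items), subject_maps


def label_networks(
    components: ComponentSet,
    templates: dict[str, np.ndarray],
    threshold: float = 0.25,
    artifact_indices: set[int] | None = None,
) -> ComponentSet:
    """Assign each component the template label with the highest spatial |r|.

    Components are retained only if their best |r| reaches ``threshold``
    and they are not flagged as artifacts; when several components match
    one template label, only the best match is kept.
    """
    if not templates:
        raise ArgumentError("templates must be nonempty")
    artifact_indices = artifact_indices or set()
    tnames = list(templates)
    tmat = np.stack([np.asarray(templates[t], dtype=float) for t in tnames])
    if tmat.shape[1] != components.group_maps.shape[1]:
        raise ArgumentError("templates and components are on different masks")
    n = components.n_components
    best_label = {}
    for i in range(n):
        if i in artifact_indices:
            continue
        rs = np.array(
            [abs(np.corrcoef(components.group_maps[i], t)[0, 1]) for t in tmat]
        )
        j = int(rs.argmax())
        if rs[j] >= threshold:
            lab = tnames[j]
            if lab not in best_label or rs[j] > best_label[lab][1]:
                best_label[lab] = (i, float(rs[j]))
    keep = sorted(best_label.values())
    idx = [i for i, _ in keep]
    labels = tuple(lab for lab, (i, _) in sorted(best_label.items(), key=lambda kv: kv[1][0]))
    return ComponentSet(
        group_maps=components.group_maps[idx],
        stability=None if components.stability is None else components.stability[idx],
        labels=labels,
        converged=components.converged,
    )


def run_gica(dataset: FourDDataset, config: GicaConfig) -> tuple[ComponentSet, TimeCourseSet]:
    """Full decomposition: two-stage PCA, ICASSO-stabilized Infomax,
    back-reconstruction."""
    reduced = two_stage_pca(dataset, config.n_pc, config.n_ic)
    comps = icasso_stability(reduced.group, config)
    tcs, subject_maps = back_reconstruct(dataset, comps.group_maps)
    comps.subject_maps = subject_maps
    comps.subject_timecourses = {
        f"{tc.subject}_{tc.session}": tc.data for tc in tcs
    }
    return comps, tcs


def load_nifti_dataset(paths: dict[str, str], mask_path: str) -> FourDDataset:
    """Load per-subject 4-D NIfTI files and a binary mask into matrices."""
    import nibabel as nib

    mask_img = nib.load(mask_path)
    mask = np.asarray(mask_img.dataobj).astype(bool).reshape(-1)
    data, ids = [], []
    for sid, p in sorted(paths.items()):
        img = nib.load(p)
        vol = np.asarray(img.dataobj, dtype=float)
        flat = vol.reshape(-1, vol.shape[-1])
        data.append(flat[mask])
        ids.append(sid)
    return FourDDataset(data=data, subject_ids=ids, mask=mask)
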