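"""In-memory containers passed between pipeline stages.

The pipeline's main currency is component time courses: one matrix of shape
(components, TRs) per subject and session, plus connectivity derivatives
(static FNC matrices, windowed FNC arrays, state sequences).  Containers are
thin dataclasses over numpy arrays with the file round-trips used by the
command-line stages (TSV for time courses, CSV/JSON for derived objects).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError

#: canonical labels of the 14 large-scale networks used throughout:
#: frontoparietal (right/left), default mode (anterior/posterior),
#: visual (medial/posterior), cerebellar, dorsal attention, sensorimotor
#: (dorsal/ventral), auditory, salience (x2), subcortical.
NETWORK_LABELS: tuple[str, ...] = (
    "rFPN", "lFPN", "aDMN", "pDMN", "mVN", "pVN", "CBN",
    "DAN", "dSMN", "vSMN", "AUD", "SN1", "SN2", "SCN",
)

SESSIONS = ("pre", "post")


def pair_indices(n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular (i, j) index arrays, i < j, in row-major order."""
    return np.triu_indices(n_components, k=1)


def pair_labels(labels: Sequence[str]) -> list[str]:
    """Names of all unordered component pairs, ``"a-b"`` with i < j."""
    ii, jj = pair_indices(len(labels))
    return [f"{labels[i]}-{labels[j]}" for i, j in zip(ii, jj)]


def matrix_to_pairs(mat: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle of a square matrix to a pair vector."""
    ii, jj = pair_indices(mat.shape[0])
    return mat[ii, jj]


def pairs_to_matrix(vec: np.ndarray, n_components: int) -> np.ndarray:
    """Inverse of :func:`matrix_to_pairs`; diagonal is NaN."""
    mat = np.full((n_components, n_components), np.nan)
    ii, jj = pair_indices(n_components)
    mat[ii, jj] = vec
    mat[jj, ii] = vec
    return mat


@dataclass
class TimeCourses:
    """Component time courses of one subject-session.

    ``data`` has shape (n_components, n_timepoints); ``tr_seconds`` is the
    sampling interval.
    """

    subject: str
    session: str
    data: np.ndarray
    tr_seconds: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ArgumentError("time courses must be a 2-D (components x TRs) array")
        if self.data.shape[0] != len(self.labels):
            raise ArgumentError(
                f"{self.data.shape[0]} rows but {len(self.labels)} component labels"
            )
        if self.session not in SESSIONS:
            raise ArgumentError(f"session must be one of {SESSIONS}, got {self.session!r}")

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.data.T, columns=list(self.labels))
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, subject: str, session: str, tr_seconds: float
    ) -> "TimeCourses":
        df = pd.read_csv(path, sep="\t")
        return cls(
            subject=subject,
            session=session,
            data=df.to_numpy().T,
            tr_seconds=tr_seconds,
            labels=tuple(df.columns),
        )


class TimeCourseSet:
    """Ordered collection of :class:`TimeCourses` across subjects/sessions."""

    def __init__(self, items: Sequence[TimeCourses]):
        self._items = list(items)
        keys = [(tc.subject, tc.session) for tc in self._items]
        if len(set(keys)) != len(keys):
            raise ArgumentError("duplicate (subject, session) entries")
        self._index = {k: i for i, k in enumerate(keys)}

    def __iter__(self) -> Iterator[TimeCourses]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def get(self, subject: str, session: str) -> TimeCourses:
        return self._items[self._index[(subject, session)]]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for tc in self._items:
            seen.setdefault(tc.subject, None)
        return list(seen)

    def filter(self, session: str | None = None) -> "TimeCourseSet":
        items = [tc for tc in self._items if session is None or tc.session == session]
        return TimeCourseSet(items)

    def map(self, fn) -> "TimeCourseSet":
        return TimeCourseSet([fn(tc) for tc in self._items])

    def save(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for tc in self._items:
            p = directory / f"sub-{tc.subject}_ses-{tc.session}_timecourses.tsv"
            tc.to_tsv(p)
            paths.append(p)
        return paths

    @classmethod
    def load(cls, directory: str | Path, tr_seconds: float) -> "TimeCourseSet":
        directory = Path(directory)
        items = []
        for p in sorted(directory.glob("sub-*_ses-*_timecourses.tsv")):
            stem = p.name.removesuffix("_timecourses.tsv")
            sub = stem.split("_")[0].removeprefix("sub-")
            ses = stem.split("_")[1].removeprefix("ses-")
            items.append(TimeCourses.from_tsv(p, sub, ses, tr_seconds))
        return cls(items)


@dataclass
class SFNCMatrix:
    """Static FNC: Fisher-z correlations between component time courses."""

    subject: str
    session: str
    values: np.ndarray  # (C, C), symmetric, NaN diagonal
    labels: tuple[str, ...]

    def pair_vector(self) -> np.ndarray:
        return matrix_to_pairs(self.values)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, float_format="%.10g"
        )


@dataclass
class WindowedFNC:
    """Dynamic FNC of one subject-session: (windows, pairs) Fisher-z array.

    Window start indices are 0-based TRs; window ``s`` covers the half-open
    TR range ``[s, s + length)``.  Pair order is the strict upper triangle
    in row-major order (see :func:`pair_indices`).
    """

    subject: str
    session: str
    values: np.ndarray  # (n_windows, n_pairs)
    window_starts: np.ndarray
    labels: tuple[str, ...]
    window_length: int
    sigma: float
    step: int
    tr_seconds: float
    fisher_z: bool = True

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        ii, jj = pair_indices(len(self.labels))
        rows = []
        for w, start in enumerate(self.window_starts):
            rows.append(
                pd.DataFrame(
                    {
                        "window_start": start,
                        "pair_i": [self.labels[i] for i in ii],
                        "pair_j": [self.labels[j] for j in jj],
                        "z": self.values[w],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
        sidecar = Path(str(path)).with_suffix(".json")
        meta = {
            "window_length": self.window_length,
            "sigma": self.sigma,
            "step": self.step,
            "n_windows": int(self.n_windows),
            "n_timepoints": int(self.window_starts[-1]) + self.window_length,
            "tr_seconds": self.tr_seconds,
            "fisher_z": self.fisher_z,
        }
        sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1))


@dataclass
class ExemplarSet:
    """High-variance windows pooled across subject-sessions for clustering."""

    vectors: np.ndarray  # (n_exemplars, n_pairs)
    provenance: list[tuple[str, str, int]]  # (subject, session, window_start)

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class StateModel:
    """Fitted connectivity-state vocabulary."""

    k: int
    centroids: np.ndarray  # (k, n_pairs)
    metric: str
    elbow_curve: dict[int, float]
    n_replicates: int
    seed: int
    objective: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "metric": self.metric,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "objective": self.objective,
            "elbow_curve": {str(k): v for k, v in sorted(self.elbow_curve.items())},
            "centroids": self.centroids.tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StateModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            centroids=np.asarray(d["centroids"]),
            metric=d["metric"],
            elbow_curve={int(k): v for k, v in d["elbow_curve"].items()},
            n_replicates=d["n_replicates"],
            seed=d["seed"],
            objective=d.get("objective", float("nan")),
        )


@dataclass
class StateSequence:
    """Per-window state assignment of one subject-session (0-based states)."""

    subject: str
    session: str
    states: np.ndarray
    window_starts: np.ndarray


@dataclass
class StateMetrics:
    """The four state-transition summaries of one state sequence.

    ``mean_dwell`` is NaN for unvisited states; ``transition_matrix`` rows
    are NaN when the state never emits an outgoing step.
    """

    fractional_time: np.ndarray  # (k,)
    mean_dwell: np.ndarray  # (k,) windows
    n_transitions: int
    transition_matrix: np.ndarray  # (k, k) row-stochastic where defined


@dataclass
class FourDDataset:
    """Masked multi-subject volumetric data as voxel x time matrices."""

    data: list[np.ndarray]  # each (n_voxels, n_timepoints)
    subject_ids: list[str]
    mask: np.ndarray  # boolean, flattened voxel mask

    def __post_init__(self) -> None:
        if len(self.data) != len(self.subject_ids):
            raise ArgumentError("one matrix per subject id required")
        v = int(self.mask.sum())
        for sid, x in zip(self.subject_ids, self.data):
            if x.shape[0] != v:
                raise ArgumentError(f"subject {sid}: {x.shape[0]} voxels but mask has {v}")
        t0 = self.data[0].shape[1]
        if any(x.shape[1] != t0 for x in self.data):
            raise ArgumentError("all subjects must share the same time length")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_timepoints(self) -> int:
        return self.data[0].shape[1]


@dataclass
class ComponentSet:
    """Group decomposition result: maps, subject time courses, stability."""

    group_maps: np.ndarray  # (n_ic, n_voxels)
    subject_timecourses: dict[str, np.ndarray] = field(default_factory=dict)
    subject_maps: dict[str, np.ndarray] = field(default_factory=dict)
    stability: np.ndarray | None = None
    labels: tuple[str, ...] | None = None
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]
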