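"""Desk-scale recovery benchmarks on the synthetic cohort.

Each function regenerates its inputs from a seed, runs the relevant slice
of the pipeline at the protocol's parameters (window length 30 TRs, sigma
3 TRs, step 1 TR; k scanned over 2..10 with 150 k-means replicates), and
returns what was recovered.  They are used both by the acceptance tests
and by ``scripts/acceptance.py``.
"""
from __future__ import annotations

import numpy as np

from . import connectivity as conn
from . import states as st
from .synth import CohortConfig, simulate_timecourses

#: cohort size used for clustering benchmarks: 20 subjects x 2 sessions
#: = 40 subject-sessions of 230 TRs each
BENCH_N_SUBJECTS = 20


def cohort_windowed_fnc(config: CohortConfig, window_length: int = 30, sigma: float = 3.0,
                        step: int = 1):
    """Simulate a cohort and return its cleaned windowed FNC plus truth."""
    tcs, truth = simulate_timecourses(config)
    taper = conn.build_taper(window_length, sigma)
    wfncs = [
        conn.windowed_fnc(conn.clean_timecourses(tc), taper, step=step) for tc in tcs
    ]
    return wfncs, truth


def elbow_k_for_seed(seed: int, n_subjects: int = BENCH_N_SUBJECTS,
                     n_replicates: int = 150) -> int:
    """Planted-state-count recovery: selected k for one cohort seed."""
    config = CohortConfig(n_subjects=n_subjects, seed=seed)
    wfncs, _ = cohort_windowed_fnc(config)
    exemplars = st.select_exemplars(wfncs)
    model = st.choose_k_elbow(exemplars, n_replicates=n_replicates, seed=seed)
    return model.k


def elbow_k_majority(seed: int, n_seeds: int = 10,
                     n_subjects: int = BENCH_N_SUBJECTS,
                     n_replicates: int = 150) -> tuple[int, list[int]]:
    """Majority-vote selected k over ``n_seeds`` independent cohorts.

    Cohort seeds are derived from ``seed`` so the whole benchmark is
    reproducible from a single integer.
    """
    rng = np.random.default_rng(seed)
    cohort_seeds = [int(s) for s in rng.integers(2**31, size=n_seeds)]
    ks = [elbow_k_for_seed(s, n_subjects=n_subjects, n_replicates=n_replicates)
          for s in cohort_seeds]
    values, counts = np.unique(ks, return_counts=True)
    return int(values[counts.argmax()]), ks


def state_assignment_accuracy(seed: int, n_subjects: int = BENCH_N_SUBJECTS,
                              n_replicates: int = 150) -> float:
    """Window-level state recovery under the best majority mapping.

    Clusters a cohort at the planted k, maps each estimated state to the
    planted state it most often co-occurs with (window labels are taken as
    the planted state at the window's centre TR), and returns the fraction
    of windows assigned correctly.
    """
    config = CohortConfig(n_subjects=n_subjects, seed=seed)
    wfncs, truth = cohort_windowed_fnc(config)
    exemplars = st.select_exemplars(wfncs)
    centroids, _, _, _ = st.cluster_exemplars(
        exemplars, k=config.n_states, n_replicates=n_replicates, seed=seed
    )
    model = st.StateModel(
        k=config.n_states, centroids=centroids, metric="cityblock",
        elbow_curve={}, n_replicates=n_replicates, seed=seed,
    )
    sequences = st.assign_windows(wfncs, model)
    half = wfncs[0].window_length // 2
    confusion = np.zeros((config.n_states, config.n_states))
    for seq in sequences:
        planted = truth.state_sequences[(seq.subject, seq.session)]
        centers = seq.window_starts + half
        np.add.at(confusion, (seq.states, planted[centers]), 1.0)
    mapping = confusion.argmax(axis=1)
    correct = sum(confusion[s, mapping[s]] for s in range(config.n_states))
    return float(correct / confusion.sum())
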