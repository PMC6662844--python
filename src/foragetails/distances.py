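"""Turn search paths into inter-item distance series.

Visual cancellation paths yield straight-line (Euclidean) distances in
millimetres between consecutively cancelled targets.  Semantic fluency
lists yield ``1 - cosine similarity`` between the word vectors of
consecutive productions, with inter-response times (IRTs) attached to
each retained transition.  Immediate repetitions (identical consecutive
tokens) sit at distance exactly 0.  Transitions involving an
out-of-vocabulary token are skipped (not the whole list) and counted.

Note on range: cosine similarity of arbitrary real vectors lies in
[-1, 1], so the semantic distance lies in [0, 2].  No clipping is
applied — the upper tail is precisely the analysis target.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import SearchPath, Task
from .embeddings import EmbeddingTable, OutOfVocabularyError, normalize_token


@dataclasses.dataclass
class DistanceSeries:
    """Consecutive-transition distances for one participant's path."""

    participant_id: str
    task: Task
    distances: np.ndarray
    irts: np.ndarray | None = None
    skipped_pairs: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.irts is not None:
            self.irts = np.asarray(self.irts, dtype=float)
            if len(self.irts) and len(self.irts) != len(self.distances):
                raise ValueError("distances and irts must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.distances)


def euclidean_path_distances(path: SearchPath) -> DistanceSeries:
    """Straight-line distance (mm) between consecutive cancelled targets."""
    if path.task is not Task.VISUAL:
        raise ValueError("euclidean_path_distances expects a visual path")
    xy = path.coordinates
    if len(xy) < 2:
        warnings.warn(
            f"{path.participant_id}: fewer than 2 events, empty distance series",
            stacklevel=2,
        )
        return DistanceSeries(path.participant_id, Task.VISUAL, np.empty(0))
    d = np.hypot(*np.diff(xy, axis=0).T)
    return DistanceSeries(path.participant_id, Task.VISUAL, d)


def semantic_distance(a: str, b: str, table: EmbeddingTable) -> float:
    """``1 - cos(v_a, v_b)``; exactly 0 for identical tokens.

    Raises :class:`OutOfVocabularyError` if either token is missing so the
    caller can skip the pair.
    """
    ka, kb = normalize_token(a), normalize_token(b)
    va, vb = table.vector(ka), table.vector(kb)
    if ka == kb:
        return 0.0
    sim = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return 1.0 - sim


def semantic_path_distances(path: SearchPath, table: EmbeddingTable) -> DistanceSeries:
    """Distances and IRTs over consecutive token pairs; OOV pairs skipped.

    A pair is skipped (and counted in ``skipped_pairs``) when either of
    its tokens is out of vocabulary; IRTs are attached only to retained
    pairs, so ``len(distances) == len(irts)``.
    """
    if path.task is not Task.SEMANTIC:
        raise ValueError("semantic_path_distances expects a semantic path")
    events = path.events
    if len(events) < 2:
        warnings.warn(
            f"{path.participant_id}: fewer than 2 events, empty distance series",
            stacklevel=2,
        )
        return DistanceSeries(path.participant_id, Task.SEMANTIC, np.empty(0), np.empty(0))
    dists: list[float] = []
    irts: list[float] = []
    skipped = 0
    have_t = all(ev.t is not None for ev in events)
    for prev, cur in zip(events, events[1:]):
        try:
            d = semantic_distance(prev.token, cur.token, table)
        except OutOfVocabularyError:
            skipped += 1
            continue
        dists.append(d)
        if have_t:
            irts.append(cur.t - prev.t)
    if not dists:
        warnings.warn(f"{path.participant_id}: all pairs out of vocabulary", stacklevel=2)
    return DistanceSeries(
        path.participant_id,
        Task.SEMANTIC,
        np.asarray(dists),
        np.asarray(irts) if have_t else None,
        skipped_pairs=skipped,
    )


def count_repetitions(path: SearchPath) -> tuple[int, int]:
    """(immediate, distant) repetition counts in a semantic production list.

    Immediate: same token as the directly preceding one (e.g. dog-dog).
    Distant: token produced earlier in the list but not at the preceding
    position.
    """
    tokens = [normalize_token(t) for t in path.tokens]
    immediate = distant = 0
    seen: set[str] = set()
    for i, tok in enumerate(tokens):
        if i > 0 and tok == tokens[i - 1]:
            immediate += 1
        elif tok in seen:
            distant += 1
        seen.add(tok)
    return immediate, distant


def distances_frame(series: Iterable[DistanceSeries]) -> pd.DataFrame:
    """Long-format table: ``participant_id,task,pair_index,distance,irt_sec``."""
    rows = []
    for s in series:
        irts = s.irts if s.irts is not None and len(s.irts) else [None] * len(s)
        for j, (d, irt) in enumerate(zip(s.distances, irts)):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "task": s.task.value,
                    "pair_index": j,
                    "distance": d,
                    "irt_sec": irt,
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "task", "pair_index", "distance", "irt_sec"])


def write_distances(series: Sequence[DistanceSeries], path: str | Path, seed: int | None = None) -> None:
    from . import __version__

    with Path(path).open("w") as fh:
        fh.write(f"# generated-by foragetails {__version__} seed={seed}\n")
        distances_frame(series).to_csv(fh, index=False)
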