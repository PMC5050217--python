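"""Independent infection-episode tabulation via the waiting-list decision tree.

Consecutive infection records for one patient may document a single
ongoing infection rather than independent events. To count independent
episodes, every record sits on a "waiting list" after its onset day: a
later record within 6 days of a similar waiting record (same infection
type, mode, and pathogen) — or within 2 days of a dissimilar one — is an
extension of that record's episode; otherwise it opens a new episode.
Each joining record re-arms its episode's window from its own day.

Patients with >= 3 cumulative episodes form the hypersusceptible case
group; patients with <= 2 are non-cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cohort_io import InfectionRecord

__all__ = [
    "WaitingListPolicy",
    "EpisodeTally",
    "similar",
    "tabulate_episodes",
    "classify_hypersusceptible",
    "HYPERSUSCEPTIBLE_THRESHOLD",
]

HYPERSUSCEPTIBLE_THRESHOLD = 3

SIMILARITY_FIELDS = ("itype", "mode", "pathogen")


@dataclass(frozen=True)
class WaitingListPolicy:
    """Windows (days) of the waiting-list rule.

    ``similar_window`` applies when two records match on every field in
    ``similarity_fields``; ``dissimilar_window`` otherwise. The boundary
    is inclusive: a gap exactly equal to the window still extends.
    """

    similar_window: float = 6.0
    dissimilar_window: float = 2.0
    similarity_fields: tuple[str, ...] = SIMILARITY_FIELDS

    def __post_init__(self) -> None:
        if self.similar_window <= 0 or self.dissimilar_window <= 0:
            raise ValueError("windows must be positive")
        if self.similar_window < self.dissimilar_window:
            raise ValueError("similar_window must be >= dissimilar_window")
        unknown = set(self.similarity_fields) - set(SIMILARITY_FIELDS)
        if unknown:
            raise ValueError(f"unknown similarity fields: {sorted(unknown)}")


@dataclass
class EpisodeTally:
    """Per-patient episode count plus an audit of record-to-episode assignment.

    ``assignment`` maps each input record index (original order) to its
    episode index; episodes are numbered 0..n-1 in onset order.
    """

    patient_id: str
    n_episodes: int
    assignment: dict[int, int] = field(default_factory=dict)


def similar(a: InfectionRecord, b: InfectionRecord,
            policy: WaitingListPolicy | None = None) -> bool:
    """True iff all similarity fields match and none is "unknown".

    An "unknown" value never matches anything, including another
    "unknown" — conservatively forcing the short window, since there is
    no evidence the two records share a cause.
    """
    policy = policy or WaitingListPolicy()
    for f in policy.similarity_fields:
        va, vb = getattr(a, f), getattr(b, f)
        if va == "unknown" or vb == "unknown" or va != vb:
            return False
    return True


def tabulate_episodes(records: Sequence[InfectionRecord],
                      policy: WaitingListPolicy | None = None) -> EpisodeTally:
    """Merge one patient's infection records into independent episodes.

    Records are processed in nondecreasing day order (ties by input
    order, then infection type). A candidate joins the episode of the
    most recent prior record still waiting for it — a prior record waits
    while the day gap is within the similar or dissimilar window as
    appropriate — and its own day becomes a fresh anchor for that
    episode. With no waiting record, the candidate opens a new episode.
    """
    policy = policy or WaitingListPolicy()
    if not records:
        return EpisodeTally(patient_id="", n_episodes=0)
    pids = {r.patient_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}")

    order = sorted(range(len(records)),
                   key=lambda i: (records[i].day, i, records[i].itype))

    assignment: dict[int, int] = {}
    n_episodes = 0
    for pos, idx in enumerate(order):
        c = records[idx]
        best: tuple[float, int] | None = None  # (day, episode) of join target
        for prev_idx in order[:pos]:
            r = records[prev_idx]
            window = (policy.similar_window if similar(r, c, policy)
                      else policy.dissimilar_window)
            if c.day - r.day <= window:
                ep = assignment[prev_idx]
                # most recent waiting record wins; on equal days the
                # lower episode index wins
                if best is None or (r.day, -ep) > (best[0], -best[1]):
                    best = (r.day, ep)
        if best is None:
            assignment[idx] = n_episodes
            n_episodes += 1
        else:
            assignment[idx] = best[1]
    return EpisodeTally(patient_id=records[0].patient_id,
                        n_episodes=n_episodes, assignment=assignment)


def classify_hypersusceptible(tally: EpisodeTally,
                              threshold: int = HYPERSUSCEPTIBLE_THRESHOLD) -> bool:
    """True iff the patient accumulated >= ``threshold`` independent episodes."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return tally.n_episodes >= threshold
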