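"""Experimental schema for the overlapping-events encoding paradigm.

The design encodes movie triads (AB / BC / XY), their repetition structure,
the fixed within-movie segment schedule, and the channel layout with its
neighbor graph.  Movies come in triads: each AB movie shares its "B"
character with exactly one BC movie (same ``triad_id``), while XY movies are
entirely novel controls.  Time zero is the onset of the first Sim display;
the 1-s leading fixation cross occupies [-1, 0) and is only partially inside
the epoch window.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

#: Canonical segment schedule (name, start_s, end_s).  Durations 2/3/1/2/5 s
#: tile [0, 13] without overlap.  For AB movies the segments show Sim A; for
#: BC movies they show Sim C (Sim Y for XY movies).
SEGMENT_TABLE: tuple[tuple[str, float, float], ...] = (
    ("sim_first", 0.0, 2.0),
    ("sim_first_context", 2.0, 5.0),
    ("fixation", 5.0, 6.0),
    ("sim_second", 6.0, 8.0),
    ("joint_context", 8.0, 13.0),
)

#: The four AB-movie segments used for coherence feature selection
#: ("Sim A", "Sim A in Context", "Sim B", "Sim A and B in Context").
AB_SEGMENTS: tuple[str, ...] = (
    "sim_first",
    "sim_first_context",
    "sim_second",
    "joint_context",
)

EPOCH_WINDOW: tuple[float, float] = (-0.5, 13.5)

ROLES = ("AB", "BC", "XY")


@dataclass(frozen=True)
class Movie:
    movie_id: str
    role: str
    triad_id: int


@dataclass
class ExperimentDesign:
    """Movie set, repetition count, segment schedule and channel layout."""

    n_triads: int
    n_repetitions: int
    sample_rate_hz: float
    movies: list[Movie]
    channel_names: list[str]
    neighbor_graph: dict[str, tuple[str, ...]]
    segment_table: tuple[tuple[str, float, float], ...] = SEGMENT_TABLE
    epoch_window: tuple[float, float] = EPOCH_WINDOW

    def movies_by_role(self, role: str) -> list[Movie]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        return [m for m in self.movies if m.role == role]

    def movie(self, movie_id: str) -> Movie:
        for m in self.movies:
            if m.movie_id == movie_id:
                return m
        raise KeyError(f"unknown movie_id {movie_id!r}")

    def corresponding_bc(self, ab_movie_id: str) -> Movie:
        """BC movie sharing the triad (the overlapping B character)."""
        ab = self.movie(ab_movie_id)
        if ab.role != "AB":
            raise ValueError(f"{ab_movie_id!r} has role {ab.role}, expected AB")
        (bc,) = [m for m in self.movies if m.role == "BC" and m.triad_id == ab.triad_id]
        return bc

    def segment_window(self, name: str) -> tuple[float, float]:
        for seg, lo, hi in self.segment_table:
            if seg == name:
                return (lo, hi)
        raise KeyError(f"unknown segment {name!r}")

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window
        return int(round((hi - lo) * self.sample_rate_hz))

    def time_axis(self) -> np.ndarray:
        lo, _ = self.epoch_window
        return lo + np.arange(self.n_samples) / self.sample_rate_hz

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "n_triads": self.n_triads,
            "n_repetitions": self.n_repetitions,
            "sample_rate_hz": self.sample_rate_hz,
            "movies": [[m.movie_id, m.role, m.triad_id] for m in self.movies],
            "channel_names": list(self.channel_names),
            "neighbor_graph": {k: list(v) for k, v in self.neighbor_graph.items()},
            "segment_table": [list(row) for row in self.segment_table],
            "epoch_window": list(self.epoch_window),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        d = json.loads(text)
        return cls(
            n_triads=d["n_triads"],
            n_repetitions=d["n_repetitions"],
            sample_rate_hz=d["sample_rate_hz"],
            movies=[Movie(*row) for row in d["movies"]],
            channel_names=list(d["channel_names"]),
            neighbor_graph={k: tuple(v) for k, v in d["neighbor_graph"].items()},
            segment_table=tuple(tuple(row) for row in d["segment_table"]),
            epoch_window=tuple(d["epoch_window"]),
        )

    def segments_tsv(self) -> str:
        """BED-like TSV of the segment schedule for auditability."""
        lines = ["segment\tstart_s\tend_s"]
        lines += [f"{s}\t{lo:g}\t{hi:g}" for s, lo, hi in self.segment_table]
        return "\n".join(lines) + "\n"


@dataclass
class PairSet:
    """Enumerated (movie, repetition) pairs for the coherence contrast.

    Within-movie pairs compare repetitions of one movie (rep_1 < rep_2);
    between-movie pairs compare an anchor movie with every other AB movie
    under the same unordered repetition-index scheme, so a 24-movie,
    5-repetition design yields 10 within and 230 between pairs per movie.
    """

    pair_kind: str  # "within_movie" | "between_movie"
    pairs: list[tuple[tuple[str, int], tuple[str, int]]]

    def __len__(self) -> int:
        return len(self.pairs)


def _ring_grid_layout(channels: list[str]) -> dict[str, tuple[str, ...]]:
    """Deterministic synthetic layout: channels on a near-square grid,
    neighbors = orthogonally adjacent grid cells."""
    n = len(channels)
    ncols = max(1, int(np.ceil(np.sqrt(n))))
    graph: dict[str, set[str]] = {c: set() for c in channels}
    for i, c in enumerate(channels):
        r, q = divmod(i, ncols)
        for dr, dq in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, qq = r + dr, q + dq
            j = rr * ncols + qq
            if rr >= 0 and 0 <= qq < ncols and 0 <= j < n:
                graph[c].add(channels[j])
    return {c: tuple(sorted(v)) for c, v in graph.items()}


def layout_from_positions(
    positions: dict[str, tuple[float, float]], scale: float = 1.3
) -> dict[str, tuple[str, ...]]:
    """Neighbor graph from 2-D channel coordinates (e.g. a JSON montage):
    channels are neighbors if closer than ``scale`` times the median
    nearest-neighbor distance."""
    names = list(positions)
    xy = np.asarray([positions[c] for c in names], float)
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = scale * float(np.median(d.min(axis=1)))
    graph = {
        names[i]: tuple(sorted(names[j] for j in np.flatnonzero(d[i] <= thresh)))
        for i in range(len(names))
    }
    return graph


def montage_layout(montage_name: str, channels: list[str]) -> dict[str, tuple[float, float]]:
    """2-D channel coordinates from a standard MNE montage name (e.g.
    "standard_1020"), restricted to ``channels``."""
    import mne

    montage = mne.channels.make_standard_montage(montage_name)
    pos3d = montage.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos3d]
    if missing:
        raise ValueError(f"channels absent from montage {montage_name!r}: {missing}")
    return {c: (float(pos3d[c][0]), float(pos3d[c][1])) for c in channels}


def build_design(
    n_triads: int,
    n_repetitions: int,
    sample_rate_hz: float,
    channels: list[str] | int,
    layout: dict[str, tuple[float, float]] | str | None = None,
    seed: int = 0,
) -> ExperimentDesign:
    """Build a design with ``n_triads`` AB + BC + XY movies each.

    ``channels`` may be a channel-name list or a count (names are then
    synthesized).  The neighbor graph comes from ``layout`` - a coordinate
    dict (e.g. loaded from a JSON montage file) or a standard montage name
    - when given, else from a deterministic synthetic grid.  Which
    second-round movies act as BC vs XY is a seeded counterbalancing
    permutation; it is metadata only and does not alter any analysis path.
    """
    if n_triads < 1 or n_repetitions < 1:
        raise ValueError("n_triads and n_repetitions must be >= 1")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    if isinstance(channels, int):
        channels = [f"ch{i:02d}" for i in range(channels)]
    channels = list(channels)
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channel names")

    rng = np.random.default_rng(seed)
    # counterbalancing flag: a permutation of which triads were "recognizable"
    order = rng.permutation(n_triads)
    movies: list[Movie] = []
    for t in range(n_triads):
        movies.append(Movie(f"AB{t:02d}", "AB", t))
    for t in order:
        movies.append(Movie(f"BC{t:02d}", "BC", int(t)))
    for t in range(n_triads):
        movies.append(Movie(f"XY{t:02d}", "XY", n_triads + t))

    if isinstance(layout, str):
        layout = montage_layout(layout, channels)
    graph = layout_from_positions(layout) if layout else _ring_grid_layout(channels)
    return ExperimentDesign(
        n_triads=n_triads,
        n_repetitions=n_repetitions,
        sample_rate_hz=float(sample_rate_hz),
        movies=movies,
        channel_names=channels,
        neighbor_graph=graph,
    )


def enumerate_within_pairs(design: ExperimentDesign, movie_id: str) -> PairSet:
    """All unordered repetition pairs of one AB movie: C(R, 2) pairs."""
    m = design.movie(movie_id)
    if m.role != "AB":
        raise ValueError(f"within pairs are defined for AB movies, got {m.role}")
    reps = range(design.n_repetitions)
    pairs = [
        ((movie_id, r1), (movie_id, r2)) for r1, r2 in itertools.combinations(reps, 2)
    ]
    return PairSet("within_movie", pairs)


def enumerate_between_pairs(design: ExperimentDesign, movie_id: str) -> PairSet:
    """Pairs of the anchor AB movie with every other AB movie, using the
    same rep_1 < rep_2 repetition scheme: (n_AB - 1) * C(R, 2) pairs."""
    m = design.movie(movie_id)
    if m.role != "AB":
        raise ValueError(f"between pairs are defined for AB movies, got {m.role}")
    reps = range(design.n_repetitions)
    others = [o.movie_id for o in design.movies_by_role("AB") if o.movie_id != movie_id]
    pairs = [
        ((movie_id, r1), (other, r2))
        for other in others
        for r1, r2 in itertools.combinations(reps, 2)
    ]
    return PairSet("between_movie", pairs)
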