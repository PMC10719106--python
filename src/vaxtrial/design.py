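"""Two-stage randomization for a blocked cluster trial with embedded placebos.

The design randomizes at two levels.  Stage one operates on villages: within
each district, villages are ranked by population, consecutive fours form
quadruplets, a fixed number of quadruplets is sampled with probability
proportional to its share of the district population, and the four arms
(placebo, health message, low cash, high cash) are randomly permuted over the
four villages of each selected quadruplet.  Stage two operates on individuals:
in every non-placebo village a fixed 25% of sampled participants are shown the
placebo video instead of the village treatment ("embedded placebos"), which
identifies within-village spillover.

All randomness flows through :class:`numpy.random.Generator` objects spawned
from a single master seed, so a plan is a pure function of
(village table, quads per district, individuals per village, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "TREATED_ARMS",
    "EMBEDDED_PLACEBO_FRACTION",
    "Village",
    "Quadruplet",
    "AssignmentPlan",
    "DesignError",
    "form_quadruplets",
    "sample_quadruplets",
    "assign_arms",
    "assign_individual_videos",
    "embedded_placebo_count",
    "randomize_trial",
    "read_village_table",
]

#: The four video arms, in canonical order.
ARMS: tuple[str, ...] = ("placebo", "health", "low_cash", "high_cash")

#: Arms whose villages carry embedded placebos.
TREATED_ARMS: tuple[str, ...] = ("health", "low_cash", "high_cash")

#: Fraction of participants in a treated village shown the placebo video.
EMBEDDED_PLACEBO_FRACTION: float = 0.25


class DesignError(ValueError):
    """Raised when a randomization request cannot be honoured."""


@dataclass(frozen=True)
class Village:
    """A village cluster: the unit of stage-one randomization."""

    village_id: str
    district_id: str
    population: int
    clinic_flag: bool = False
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.population < 1:
            raise DesignError(
                f"village {self.village_id!r} has population {self.population}; must be >= 1"
            )


@dataclass(frozen=True)
class Quadruplet:
    """Four population-adjacent villages of one district; the blocking unit."""

    quad_id: str
    members: tuple[str, str, str, str]
    pop_share: float

    def __post_init__(self) -> None:
        if len(set(self.members)) != 4:
            raise DesignError(f"quadruplet {self.quad_id!r} needs 4 distinct villages")
        if not (0.0 <= self.pop_share <= 1.0) or not math.isfinite(self.pop_share):
            raise DesignError(f"quadruplet {self.quad_id!r} has invalid pop_share {self.pop_share}")


@dataclass
class AssignmentPlan:
    """A complete two-stage assignment.

    Attributes
    ----------
    village_arm
        Map village_id -> arm, for every village in a selected quadruplet.
    individual_video
        Map individual_id -> video arm actually shown.
    individual_village
        Map individual_id -> village_id (fixed order per village, so the plan
        can be re-randomized for randomization inference).
    quadruplets
        The selected quadruplets, per district.
    excluded_villages
        Villages left over when a district list is not divisible by four.
    seed
        Master seed the plan was drawn from.
    """

    village_arm: dict[str, str]
    individual_video: dict[str, str]
    individual_village: dict[str, str]
    quadruplets: list[Quadruplet]
    excluded_villages: list[str] = field(default_factory=list)
    seed: int | None = None

    def villages_in_arm(self, arm: str) -> list[str]:
        return [v for v, a in self.village_arm.items() if a == arm]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (village assignment table, individual video table)."""
        vill = pd.DataFrame(
            {"village_id": list(self.village_arm), "arm": list(self.village_arm.values())}
        )
        indiv = pd.DataFrame(
            {
                "individual_id": list(self.individual_video),
                "village_id": [self.individual_village[i] for i in self.individual_video],
                "video": list(self.individual_video.values()),
            }
        )
        return vill, indiv

    def rerandomize(self, rng: np.random.Generator) -> "AssignmentPlan":
        """Draw a fresh assignment under the same design.

        Quadruplet membership and the set of sampled individuals are held
        fixed; only the arm permutation within each quadruplet and the
        embedded-placebo positions are re-drawn.  This is the conditional
        assignment law used for randomization inference.
        """
        new_arm: dict[str, str] = {}
        for quad in self.quadruplets:
            new_arm.update(assign_arms(quad, rng))
        # individuals grouped by village in insertion order
        by_village: dict[str, list[str]] = {}
        for ind, vid in self.individual_village.items():
            by_village.setdefault(vid, []).append(ind)
        new_video: dict[str, str] = {}
        for vid, inds in by_village.items():
            videos = assign_individual_videos(new_arm[vid], len(inds), rng)
            new_video.update(zip(inds, videos))
        return AssignmentPlan(
            village_arm=new_arm,
            individual_video=new_video,
            individual_village=dict(self.individual_village),
            quadruplets=list(self.quadruplets),
            excluded_villages=list(self.excluded_villages),
            seed=None,
        )


def form_quadruplets(
    villages: Sequence[Village], district_id: str
) -> tuple[list[Quadruplet], list[str]]:
    """Group a district's villages into quadruplets of adjacent population rank.

    Villages are sorted by descending population (ties broken by village_id
    for determinism) and consecutive blocks of four become quadruplets.  The
    leftover villages when the count is not divisible by four are excluded
    from the design and returned for reporting.

    Returns
    -------
    (quadruplets, excluded_village_ids)
    """
    members = [v for v in villages if v.district_id == district_id]
    if len(members) < 4:
        raise DesignError(
            f"district {district_id!r} has {len(members)} eligible villages; need >= 4"
        )
    ranked = sorted(members, key=lambda v: (-v.population, v.village_id))
    n_quads = len(ranked) // 4
    used = ranked[: 4 * n_quads]
    excluded = [v.village_id for v in ranked[4 * n_quads :]]
    total_pop = sum(v.population for v in used)
    quads = []
    for j in range(n_quads):
        block = used[4 * j : 4 * j + 4]
        quads.append(
            Quadruplet(
                quad_id=f"{district_id}-q{j + 1:03d}",
                members=tuple(v.village_id for v in block),  # type: ignore[arg-type]
                pop_share=sum(v.population for v in block) / total_pop,
            )
        )
    return quads, excluded


def sample_quadruplets(
    quads: Sequence[Quadruplet], k: int, rng: np.random.Generator
) -> list[Quadruplet]:
    """Sample ``k`` quadruplets without replacement, weighted by population share.

    Sequential weighted draws: at each step one quadruplet is drawn with
    probability proportional to its pop_share among those remaining, then the
    weights are renormalized.  This is the law that randomization-inference
    re-draws must share.
    """
    if k > len(quads):
        raise DesignError(f"cannot sample {k} of {len(quads)} quadruplets")
    weights = np.array([q.pop_share for q in quads], dtype=float)
    if not np.all(np.isfinite(weights)) or np.any(weights < 0):
        raise DesignError("quadruplet weights must be finite and non-negative")
    remaining = list(range(len(quads)))
    chosen: list[Quadruplet] = []
    for _ in range(k):
        w = weights[remaining]
        total = w.sum()
        if total <= 0:
            raise DesignError("remaining quadruplet weights sum to zero")
        idx = rng.choice(len(remaining), p=w / total)
        chosen.append(quads[remaining.pop(idx)])
    return chosen


def assign_arms(quad: Quadruplet, rng: np.random.Generator) -> dict[str, str]:
    """Uniformly permute the four arms over the four villages of a quadruplet."""
    perm = rng.permutation(4)
    return {vid: ARMS[perm[i]] for i, vid in enumerate(quad.members)}


def embedded_placebo_count(n: int) -> int:
    """Number of embedded placebos in a treated village of ``n`` participants.

    Fixed count round(0.25 n), rounding halves up (n = 21 gives 5), rather
    than a per-individual Bernoulli draw: this guarantees the stated 75/25
    within-village split for every village.
    """
    return int(math.floor(EMBEDDED_PLACEBO_FRACTION * n + 0.5))


def assign_individual_videos(
    village_arm: str, n: int, rng: np.random.Generator
) -> list[str]:
    """Assign videos to the ``n`` participants of one village.

    In a placebo village everyone sees the placebo.  In a treated village
    exactly ``round(0.25 n)`` participants, chosen uniformly without
    replacement, see the placebo (the embedded placebos); the rest see the
    village arm's video.
    """
    if n == 0:
        return []
    if n < 0:
        raise DesignError("n must be >= 0")
    if village_arm not in ARMS:
        raise DesignError(f"unknown arm {village_arm!r}")
    if village_arm == "placebo":
        return ["placebo"] * n
    n_placebo = embedded_placebo_count(n)
    videos = [village_arm] * n
    for pos in rng.choice(n, size=n_placebo, replace=False):
        videos[pos] = "placebo"
    return videos


def _district_rngs(seed: int, district_ids: Iterable[str]) -> dict[str, np.random.Generator]:
    """One independent substream per district, keyed by sorted district id."""
    ordered = sorted(set(district_ids))
    children = np.random.SeedSequence(seed).spawn(len(ordered))
    return {d: np.random.default_rng(s) for d, s in zip(ordered, children)}


def randomize_trial(
    villages: Sequence[Village],
    quads_per_district: int = 13,
    individuals_per_village: int = 21,
    seed: int = 0,
) -> AssignmentPlan:
    """Run the full two-stage randomization over every district.

    Districts are processed independently on per-district substreams of the
    master seed, so the plan does not depend on row order of the input table.
    Individual ids are ``"<village_id>-i<j>"`` for j = 1..individuals_per_village.
    """
    plan = AssignmentPlan(
        village_arm={},
        individual_video={},
        individual_village={},
        quadruplets=[],
        excluded_villages=[],
        seed=seed,
    )
    rngs = _district_rngs(seed, (v.district_id for v in villages))
    for district_id in sorted(rngs):
        rng = rngs[district_id]
        quads, excluded = form_quadruplets(villages, district_id)
        plan.excluded_villages.extend(excluded)
        selected = sample_quadruplets(quads, min(quads_per_district, len(quads)), rng)
        for quad in selected:
            plan.quadruplets.append(quad)
            plan.village_arm.update(assign_arms(quad, rng))
        for quad in selected:
            for vid in quad.members:
                inds = [f"{vid}-i{j + 1}" for j in range(individuals_per_village)]
                videos = assign_individual_videos(
                    plan.village_arm[vid], individuals_per_village, rng
                )
                for ind, video in zip(inds, videos):
                    plan.individual_video[ind] = video
                    plan.individual_village[ind] = vid
    return plan


def read_village_table(path) -> list[Village]:
    """Read a delimited village table (village_id, district_id, population[, lat, lon])."""
    df = pd.read_csv(path)
    required = {"village_id", "district_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"village table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Village(
                village_id=str(row.village_id),
                district_id=str(row.district_id),
                population=int(row.population),
                lat=float(row.lat) if "lat" in df.columns and pd.notna(row.lat) else None,
                lon=float(row.lon) if "lon" in df.columns and pd.notna(row.lon) else None,
            )
        )
    return out
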