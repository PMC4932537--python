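"""Consensus 4-point pharmacophore elucidation.

The model sought is a near-planar rhomb: two hydrophobic features on
opposite corners, one aromatic feature on a third corner and an H-bond
donor or acceptor projection on the fourth, with sides of roughly
4-5 A.  Elucidation enumerates every type-compatible 4-point combination
("quad") on every conformer of every active, encodes each as a 6-distance
signature, and greedily leader-clusters the signatures; the cluster
covering the most molecules defines the consensus model, whose distance
ranges are the per-component [min, max] over the cluster members.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import NoConsensusError
from .features import FeaturePoint, FeatureType, planarity_rms

#: Canonical slot ids.
SLOTS = ("HYD_a", "HYD_b", "ARO", "PROJ")

#: Fixed slot-pair order of the 6-distance signature:
#: (ab, aA, aP, bA, bP, AP).
PAIRS = (
    ("HYD_a", "HYD_b"),
    ("HYD_a", "ARO"),
    ("HYD_a", "PROJ"),
    ("HYD_b", "ARO"),
    ("HYD_b", "PROJ"),
    ("ARO", "PROJ"),
)

#: The four rhomb sides (the two diagonals ab and AP are the rest).
SIDE_PAIRS = (
    ("HYD_a", "ARO"),
    ("HYD_b", "ARO"),
    ("HYD_a", "PROJ"),
    ("HYD_b", "PROJ"),
)

#: Minimum pairwise separation of the four corners.  Thiazoles emit
#: coincident HYD and ARO centroids (double role); a rhomb corner pair at
#: distance ~0 is not a 4-point arrangement, so such quads are skipped.
MIN_CORNER_SEPARATION = 1.0  # A


@dataclass(frozen=True)
class Quad:
    """Four feature points in canonical slot order with their signature.

    Canonical order: d(HYD_a, ARO) <= d(HYD_b, ARO), ties broken by
    d(., PROJ).
    """

    points: tuple[FeaturePoint, FeaturePoint, FeaturePoint, FeaturePoint]
    signature: np.ndarray = field(compare=False)

    @property
    def proj_type(self) -> FeatureType:
        return self.points[3].type

    @property
    def planarity(self) -> float:
        return planarity_rms([p.position for p in self.points])


def _make_quad(hyd1: FeaturePoint, hyd2: FeaturePoint,
               aro: FeaturePoint, proj: FeaturePoint) -> Quad:
    d = lambda p, q: float(np.linalg.norm(p.position - q.position))
    key1 = (d(hyd1, aro), d(hyd1, proj))
    key2 = (d(hyd2, aro), d(hyd2, proj))
    a, b = (hyd1, hyd2) if key1 <= key2 else (hyd2, hyd1)
    sig = np.array([
        d(a, b), d(a, aro), d(a, proj), d(b, aro), d(b, proj), d(aro, proj),
    ])
    return Quad((a, b, aro, proj), sig)


def enumerate_quads(
    features: Sequence[FeaturePoint],
    planarity_max: float | None = None,
    min_separation: float = MIN_CORNER_SEPARATION,
) -> list[Quad]:
    """All {HYD, HYD, ARO, DON_PROJ-or-ACC_PROJ} combinations, in the
    fixed order (HYD pair, ARO, PROJ) over the input feature order.

    Quads whose corners come closer than ``min_separation`` or whose
    planarity RMS exceeds ``planarity_max`` (if given) are dropped.
    """
    hyds = [f for f in features if f.type is FeatureType.HYD]
    aros = [f for f in features if f.type is FeatureType.ARO]
    projs = [f for f in features if f.is_projection]
    out = []
    for h1, h2 in itertools.combinations(hyds, 2):
        for aro in aros:
            for proj in projs:
                quad = _make_quad(h1, h2, aro, proj)
                if min_separation > 0 and quad.signature.min() < min_separation:
                    continue
                if planarity_max is not None and quad.planarity > planarity_max:
                    continue
                out.append(quad)
    return out


@dataclass(frozen=True)
class PharmacophoreModel:
    """4 typed slots, 6 pairwise distance ranges, tolerance and a
    planarity cap.

    ``proj_type`` is ``None`` when the PROJ slot accepts either a donor
    or an acceptor projection.  Unconstrained pairs carry the range
    ``(0, inf)``.
    """

    distances: dict[tuple[str, str], tuple[float, float]]
    tolerance: float = 1.0
    planarity_max: float = 0.75
    proj_type: FeatureType | None = None

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        full = {}
        for pair in PAIRS:
            dmin, dmax = self.distances.get(pair, (0.0, math.inf))
            if dmin > dmax:
                raise ValueError(f"dmin > dmax for pair {pair}")
            full[pair] = (float(dmin), float(dmax))
        object.__setattr__(self, "distances", full)

    @property
    def ranges(self) -> np.ndarray:
        """(6, 2) array of [dmin, dmax] in signature pair order."""
        return np.array([self.distances[p] for p in PAIRS])

    def slot_types(self) -> dict[str, str]:
        proj = self.proj_type.value if self.proj_type else "PROJ"
        return {"HYD_a": "HYD", "HYD_b": "HYD", "ARO": "ARO", "PROJ": proj}

    def to_json(self, path: str | None = None) -> str:
        dist = []
        for (i, j), (dmin, dmax) in self.distances.items():
            if math.isinf(dmax) and dmin == 0.0:
                continue
            dist.append({
                "i": i, "j": j, "dmin": dmin,
                "dmax": None if math.isinf(dmax) else dmax,
            })
        doc = {
            "slots": [{"id": s, "type": t} for s, t in self.slot_types().items()],
            "distances": dist,
            "tolerance": self.tolerance,
            "planarity_max": self.planarity_max,
        }
        text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "PharmacophoreModel":
        """Load from a JSON string or a path to a model file."""
        text = source
        if not source.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        doc = json.loads(text)
        proj = next(s["type"] for s in doc["slots"] if s["id"] == "PROJ")
        distances = {
            (d["i"], d["j"]): (d["dmin"],
                               math.inf if d["dmax"] is None else d["dmax"])
            for d in doc["distances"]
        }
        return cls(
            distances=distances,
            tolerance=doc["tolerance"],
            planarity_max=doc["planarity_max"],
            proj_type=None if proj == "PROJ" else FeatureType(proj),
        )


def default_rhomb_model() -> PharmacophoreModel:
    """The general Ser/Thr-kinase rhomb: four sides constrained to
    [4.0, 5.0] A, diagonals free, planarity cap 0.75 A, tolerance 1.0 A,
    PROJ slot accepting either projection type."""
    return PharmacophoreModel(
        distances={pair: (4.0, 5.0) for pair in SIDE_PAIRS},
        tolerance=1.0,
        planarity_max=0.75,
        proj_type=None,
    )


@dataclass(frozen=True)
class ElucidationResult:
    model: PharmacophoreModel
    coverage: float
    cluster_size: int
    members: tuple[tuple[str, int, int], ...]  # (mol id, conformer idx, quad idx)


@dataclass(frozen=True)
class QuadCluster:
    """One leader cluster of quad signatures and its summary statistics."""

    index: int  # creation order
    leader: np.ndarray
    low: np.ndarray  # per-component min over members
    high: np.ndarray  # per-component max over members
    coverage_count: int  # distinct molecules contributing a member
    spread: float  # mean per-component (max - min)
    members: tuple[tuple[str, int, int], ...]  # (mol id, conf idx, quad idx)
    proj_types: frozenset

    @property
    def max_side(self) -> float:
        """Largest upper bound over the four rhomb sides."""
        side_idx = [i for i, p in enumerate(PAIRS) if p in SIDE_PAIRS]
        return float(self.high[side_idx].max())

    def to_model(self, tolerance: float, planarity_max: float) -> PharmacophoreModel:
        proj = None
        if len(self.proj_types) == 1:
            proj = next(iter(self.proj_types))
        return PharmacophoreModel(
            distances={
                pair: (float(self.low[i]), float(self.high[i]))
                for i, pair in enumerate(PAIRS)
            },
            tolerance=tolerance,
            planarity_max=planarity_max,
            proj_type=proj,
        )


def cluster_quads(
    actives: Iterable[tuple[str, Sequence[Sequence[FeaturePoint]]]],
    tau: float = 1.0,
    planarity_max: float = 0.75,
) -> list[QuadCluster]:
    """Greedy leader clustering of all quad signatures of the actives.

    Quads are enumerated in fixed (molecule, conformer, quad) order; a
    quad joins the first existing cluster whose leader signature it
    matches within ``tau`` on every one of the six components, else it
    founds a new cluster.
    """
    leaders: list[np.ndarray] = []
    leader_mat = np.empty((0, 6))
    members: list[list[tuple[int, str, int, int, Quad]]] = []

    for mi, (mol_id, conformer_features) in enumerate(actives):
        for ci, feats in enumerate(conformer_features):
            for qi, quad in enumerate(
                enumerate_quads(feats, planarity_max=planarity_max)
            ):
                if leaders:
                    diffs = np.abs(leader_mat - quad.signature).max(axis=1)
                    hits = np.nonzero(diffs <= tau)[0]
                else:
                    hits = []
                if len(hits):
                    k = int(hits[0])
                else:
                    k = len(leaders)
                    leaders.append(quad.signature)
                    leader_mat = np.vstack([leader_mat, quad.signature])
                    members.append([])
                members[k].append((mi, mol_id, ci, qi, quad))

    clusters = []
    for k, mem in enumerate(members):
        sigs = np.array([m[4].signature for m in mem])
        lo, hi = sigs.min(axis=0), sigs.max(axis=0)
        clusters.append(
            QuadCluster(
                index=k,
                leader=leaders[k],
                low=lo,
                high=hi,
                coverage_count=len({m[0] for m in mem}),
                spread=float((hi - lo).mean()),
                members=tuple((m[1], m[2], m[3]) for m in mem),
                proj_types=frozenset(m[4].proj_type for m in mem),
            )
        )
    return clusters


def elucidate(
    actives: Iterable[tuple[str, Sequence[Sequence[FeaturePoint]]]],
    tau: float = 1.0,
    min_coverage: float = 0.7,
    planarity_max: float = 0.75,
) -> ElucidationResult:
    """Derive the consensus 4-point model from a set of actives.

    ``actives`` iterates (molecule id, per-conformer feature lists).
    All quads are leader-clustered (see :func:`cluster_quads`); the
    winning cluster covers the most molecules (ties: smaller mean
    per-component spread, then earliest leader) and its per-component
    [min, max] become the model's distance ranges.  Raises
    :class:`NoConsensusError` if no cluster reaches ``min_coverage``.
    """
    actives = list(actives)
    if not actives:
        raise ValueError("at least one active is required")

    clusters = cluster_quads(actives, tau=tau, planarity_max=planarity_max)
    if not clusters:
        raise NoConsensusError(0.0, min_coverage)

    winner = max(clusters, key=lambda c: (c.coverage_count, -c.spread, -c.index))
    coverage = winner.coverage_count / len(actives)
    if coverage < min_coverage:
        raise NoConsensusError(coverage, min_coverage)

    return ElucidationResult(
        model=winner.to_model(tau, planarity_max),
        coverage=coverage,
        cluster_size=len(winner.members),
        members=winner.members,
    )
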