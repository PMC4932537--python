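"""Matching molecules against a pharmacophore model and ranking
libraries; enrichment-factor statistics.

Scoring is pure distance-box deviation: an assignment's deviation is
the maximum, over the six slot pairs, of how far the pairwise distance
falls outside the model's [dmin, dmax] range (0 when inside).  Distances
are invariant under rigid motion and reflection, so no superposition is
involved in the hit decision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .elucidate import SLOTS, PharmacophoreModel
from .errors import PhoregenError
from .features import FeaturePoint, FeatureType, planarity_rms

HIT_EPS = 1e-9

#: Slot-pair index pairs into the assignment tuple (a, b, aro, proj),
#: in signature order (ab, aA, aP, bA, bP, AP).
_PAIR_IDX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class MatchResult:
    """Best slot assignment of one conformer's features to a model."""

    mol_id: str
    conf_idx: int
    assignment: Mapping[str, FeaturePoint]
    feature_indices: tuple[int, int, int, int]
    deviation: float
    planarity: float
    hit: bool


def _slot_candidates(model: PharmacophoreModel,
                     features: Sequence[FeaturePoint]):
    hyd = [i for i, f in enumerate(features) if f.type is FeatureType.HYD]
    aro = [i for i, f in enumerate(features) if f.type is FeatureType.ARO]
    if model.proj_type is None:
        proj = [i for i, f in enumerate(features) if f.is_projection]
    else:
        proj = [i for i, f in enumerate(features) if f.type is model.proj_type]
    return hyd, aro, proj


def _pair_deviation(d: float, dmin: float, dmax: float) -> float:
    if d < dmin:
        return dmin - d
    if d > dmax:
        return d - dmax
    return 0.0


def _assignment_deviation(dist: np.ndarray, idx: tuple[int, int, int, int],
                          ranges: np.ndarray) -> float:
    dev = 0.0
    for p, (u, v) in enumerate(_PAIR_IDX):
        dev = max(dev, _pair_deviation(dist[idx[u], idx[v]],
                                       ranges[p, 0], ranges[p, 1]))
    return dev


def _result(model, features, idx, dev, mol_id, conf_idx):
    pts = [features[i] for i in idx]
    planarity = planarity_rms([p.position for p in pts])
    hit = dev <= HIT_EPS and planarity <= model.planarity_max
    return MatchResult(
        mol_id=mol_id,
        conf_idx=conf_idx,
        assignment=dict(zip(SLOTS, pts)),
        feature_indices=tuple(idx),
        deviation=dev,
        planarity=planarity,
        hit=hit,
    )


def _distance_matrix(features: Sequence[FeaturePoint]) -> np.ndarray:
    pos = np.array([f.position for f in features])
    return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)


def match(model: PharmacophoreModel, features: Sequence[FeaturePoint],
          mol_id: str = "", conf_idx: int = 0) -> MatchResult | None:
    """Minimal-deviation assignment of features to the model's slots.

    Exhaustive over type-compatible assignments with branch-and-bound
    pruning on partial distance deviations; ties broken by lexicographic
    feature-index tuple (guaranteed by the enumeration order).  Returns
    ``None`` when no type-compatible assignment exists.
    """
    features = list(features)
    if not features:
        return None
    hyd, aro, proj = _slot_candidates(model, features)
    if len(hyd) < 2 or not aro or not proj:
        return None
    dist = _distance_matrix(features)
    ranges = model.ranges
    best_dev = math.inf
    best_idx = None
    for ia in hyd:
        for ib in hyd:
            if ib == ia:
                continue
            dev_ab = _pair_deviation(dist[ia, ib], *ranges[0])
            if dev_ab >= best_dev:
                continue
            for ja in aro:
                if ja in (ia, ib):
                    continue
                dev_a = max(
                    dev_ab,
                    _pair_deviation(dist[ia, ja], *ranges[1]),
                    _pair_deviation(dist[ib, ja], *ranges[3]),
                )
                if dev_a >= best_dev:
                    continue
                for jp in proj:
                    if jp in (ia, ib, ja):
                        continue
                    dev = max(
                        dev_a,
                        _pair_deviation(dist[ia, jp], *ranges[2]),
                        _pair_deviation(dist[ib, jp], *ranges[4]),
                        _pair_deviation(dist[ja, jp], *ranges[5]),
                    )
                    if dev < best_dev:
                        best_dev = dev
                        best_idx = (ia, ib, ja, jp)
    if best_idx is None:
        return None
    return _result(model, features, best_idx, best_dev, mol_id, conf_idx)


def match_bruteforce(model: PharmacophoreModel,
                     features: Sequence[FeaturePoint],
                     mol_id: str = "", conf_idx: int = 0) -> MatchResult | None:
    """Same contract as :func:`match`, pure exhaustive search (oracle)."""
    features = list(features)
    if not features:
        return None
    hyd, aro, proj = _slot_candidates(model, features)
    dist = _distance_matrix(features)
    ranges = model.ranges
    best = None
    for ia, ib, ja, jp in itertools.product(hyd, hyd, aro, proj):
        if len({ia, ib, ja, jp}) < 4:
            continue
        dev = _assignment_deviation(dist, (ia, ib, ja, jp), ranges)
        key = (dev, (ia, ib, ja, jp))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return _result(model, features, best[1], best[0], mol_id, conf_idx)


@dataclass(frozen=True)
class ScreenRow:
    mol_id: str
    match: MatchResult | None
    hit: bool
    rank: int


@dataclass(frozen=True)
class ScreenReport:
    """Deterministic ranked report: hits first by ascending deviation,
    ties by molecule id; molecules without any assignment rank last."""

    rows: tuple[ScreenRow, ...]

    @property
    def ranked_ids(self) -> list[str]:
        return [r.mol_id for r in self.rows]

    @property
    def hits(self) -> list[ScreenRow]:
        return [r for r in self.rows if r.hit]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "mol_id\thit\tdeviation\tconf_idx\tassignment\tplanarity\n"
            )
            for r in self.rows:
                if r.match is None:
                    fh.write(f"{r.mol_id}\t0\tNA\tNA\tNA\tNA\n")
                    continue
                assign = ";".join(
                    f"{slot}={'-'.join(str(i) for i in p.source_atoms)}"
                    for slot, p in r.match.assignment.items()
                )
                fh.write(
                    f"{r.mol_id}\t{int(r.hit)}\t{r.match.deviation:.4f}\t"
                    f"{r.match.conf_idx}\t{assign}\t{r.match.planarity:.4f}\n"
                )


def screen_library(
    model: PharmacophoreModel,
    entries: Iterable[tuple[str, Sequence[Sequence[FeaturePoint]]]],
) -> ScreenReport:
    """Best match per molecule over its conformers, ranked.

    ``entries`` iterates (molecule id, per-conformer feature lists) —
    the same shape :func:`phoregen.elucidate.elucidate` consumes.
    """
    results: list[tuple[str, MatchResult | None]] = []
    for mol_id, conformer_features in entries:
        best: MatchResult | None = None
        for ci, feats in enumerate(conformer_features):
            m = match(model, feats, mol_id=mol_id, conf_idx=ci)
            if m is None:
                continue
            if best is None or (m.deviation, m.conf_idx) < (best.deviation,
                                                            best.conf_idx):
                best = m
        results.append((mol_id, best))

    # hits first (ascending deviation, ties by id), then non-hits by
    # deviation, molecules with no assignment last
    def sort_key(item):
        mol_id, m = item
        if m is None:
            return (2, math.inf, mol_id)
        return (0 if m.hit else 1, m.deviation, mol_id)
    results.sort(key=sort_key)
    rows = tuple(
        ScreenRow(mol_id=mid, match=m, hit=bool(m and m.hit), rank=i)
        for i, (mid, m) in enumerate(results)
    )
    return ScreenReport(rows)


def enrichment_factor(ranked_ids: Sequence[str] | ScreenReport,
                      labels: Mapping[str, bool],
                      top_fraction: float) -> float:
    """EF = (actives in top ceil(f*N) / ceil(f*N)) / (total actives / N)."""
    if isinstance(ranked_ids, ScreenReport):
        ranked_ids = ranked_ids.ranked_ids
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    missing = [i for i in ranked_ids if i not in labels]
    if missing:
        raise ValueError(f"labels missing for {missing[:3]}...")
    n = len(ranked_ids)
    n_actives = sum(bool(labels[i]) for i in ranked_ids)
    if n_actives == 0:
        raise PhoregenError("enrichment factor undefined: zero actives")
    top = math.ceil(top_fraction * n)
    top_actives = sum(bool(labels[i]) for i in ranked_ids[:top])
    return (top_actives / top) / (n_actives / n)
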