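"""Statistical-defect applicability domain.

Each attribute gets a defect d_k measuring how unevenly it is represented
across the active training (A), passive training (P) and calibration (C)
sets:

    d_k =   |P_A - P_P| / (N_A + N_P)
          + |P_A - P_C| / (N_A + N_C)
          + |P_P - P_C| / (N_P + N_C)

where N is the number of compounds of a set containing the attribute and
P = N / set size.  A compound's defect D_j sums d_k over its distinct
non-blocked attributes; a compound is inside the applicability domain if
D_j < 2 * mean(D_j over the A+P+C reference population).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .chem_graph import AttributeKey
from .data_io import Dataset, SplitAssignment
from .errors import InvariantError

__all__ = [
    "AttributeStats",
    "DomainReport",
    "attribute_stats",
    "attribute_defect",
    "compound_defect",
    "domain_mask",
    "domain_report",
]


@dataclass(frozen=True)
class AttributeStats:
    freq_a: int
    freq_p: int
    freq_c: int
    size_a: int
    size_p: int
    size_c: int

    def __post_init__(self):
        for f, s in ((self.freq_a, self.size_a), (self.freq_p, self.size_p), (self.freq_c, self.size_c)):
            if not (0 <= f <= s):
                raise InvariantError(f"frequency {f} outside [0, {s}]")

    @property
    def prob_a(self) -> float:
        return self.freq_a / self.size_a

    @property
    def prob_p(self) -> float:
        return self.freq_p / self.size_p

    @property
    def prob_c(self) -> float:
        return self.freq_c / self.size_c


def attribute_stats(
    features: Mapping[str, Counter], split: SplitAssignment
) -> dict[AttributeKey, AttributeStats]:
    """Per-attribute compound frequencies over the A, P and C sets."""
    sets = {r: split.ids_with_role(r) for r in "APC"}
    sizes = {r: len(ids) for r, ids in sets.items()}
    freq: dict[str, Counter] = {r: Counter() for r in "APC"}
    for r, ids in sets.items():
        for cid in ids:
            freq[r].update(set(features[cid]))
    keys: set[AttributeKey] = set()
    for cid in split.role:
        keys.update(features[cid])
    return {
        k: AttributeStats(
            freq_a=freq["A"].get(k, 0),
            freq_p=freq["P"].get(k, 0),
            freq_c=freq["C"].get(k, 0),
            size_a=sizes["A"],
            size_p=sizes["P"],
            size_c=sizes["C"],
        )
        for k in keys
    }


def attribute_defect(stats: AttributeStats) -> float:
    """Defect d_k of one attribute; zero-denominator terms contribute 0."""
    terms = [
        (abs(stats.prob_a - stats.prob_p), stats.freq_a + stats.freq_p),
        (abs(stats.prob_a - stats.prob_c), stats.freq_a + stats.freq_c),
        (abs(stats.prob_p - stats.prob_c), stats.freq_p + stats.freq_c),
    ]
    return sum(num / den for num, den in terms if den > 0)


def compound_defect(
    attrs: Counter,
    defects: Mapping[AttributeKey, float],
    blocked: frozenset[AttributeKey] | set[AttributeKey],
    per_occurrence: bool = False,
) -> float:
    """Compound defect D_j: sum of d_k over the non-blocked attributes.

    By default each distinct attribute contributes once; with
    ``per_occurrence`` it contributes per occurrence.  Attributes without
    statistics (absent from A, P and C) contribute 0.
    """
    total = 0.0
    for key, count in attrs.items():
        if key in blocked:
            continue
        d = defects.get(key, 0.0)
        total += d * (count if per_occurrence else 1)
    return total


@dataclass
class DomainReport:
    """Per-compound defects and domain membership.

    ``d_mean`` is the mean defect of the reference population (A+P+C);
    a compound is in-domain iff its defect is < 2 * d_mean.  When every
    reference defect is exactly 0 there is nothing to exceed and all
    compounds are in-domain.
    """

    defect: dict[str, float]
    in_domain: dict[str, bool]
    d_mean: float
    all_blocked: set[str]

    def n_inside(self, ids=None) -> int:
        ids = self.in_domain if ids is None else ids
        return sum(self.in_domain[i] for i in ids)


def domain_mask(reference_defects, query_defects) -> tuple[float, list[bool]]:
    """Domain cutoff from a reference population applied to queries.

    Returns (mean reference defect, in-domain flags for the queries).
    """
    ref = np.asarray(list(reference_defects), dtype=float)
    if ref.size == 0:
        raise InvariantError("empty reference population")
    d_mean = float(ref.mean())
    queries = np.asarray(list(query_defects), dtype=float)
    if d_mean == 0.0:
        flags = [True] * len(queries)
    else:
        flags = list(queries < 2.0 * d_mean)
    return d_mean, [bool(f) for f in flags]


def domain_report(
    ds: Dataset,
    split: SplitAssignment,
    features: Mapping[str, Counter],
    blocked: frozenset[AttributeKey] | set[AttributeKey] = frozenset(),
    per_occurrence: bool = False,
) -> DomainReport:
    """Full applicability-domain assessment of a dataset under a split."""
    stats = attribute_stats(features, split)
    defects = {k: attribute_defect(s) for k, s in stats.items()}
    d_j: dict[str, float] = {}
    all_blocked: set[str] = set()
    for c in ds:
        attrs = features[c.id]
        d_j[c.id] = compound_defect(attrs, defects, blocked, per_occurrence)
        if attrs and all(k in blocked for k in attrs):
            all_blocked.add(c.id)
    ref_ids = [cid for cid, r in split.role.items() if r in "APC"]
    d_mean, _ = domain_mask([d_j[i] for i in ref_ids], [0.0])
    if d_mean == 0.0:
        in_domain = {cid: True for cid in d_j}
    else:
        in_domain = {cid: d < 2.0 * d_mean for cid, d in d_j.items()}
    return DomainReport(defect=d_j, in_domain=in_domain, d_mean=d_mean, all_blocked=all_blocked)
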