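"""Monte Carlo optimization of correlation weights.

The model is ``endpoint = c0 + c1 * DCW`` where ``DCW`` is the sum of
per-attribute correlation weights over a compound's attribute multiset
(S_k, SS_k and NNC_k families).  Attributes seen in fewer than ``T``
active-training compounds are *rare*: blocked, weight pinned to 0.

The optimizer is a greedy coordinate-ascent Monte Carlo: weights start
uniformly at random in ``[init_low, init_high]``; each epoch visits the
active attributes in a fresh seeded random order and, for each, evaluates
the target function at ``w - step``, ``w`` and ``w + step`` (refitting
``c0, c1`` on the active training set for each candidate) and keeps the
best.  The target function is

    TF = R2_A + R2_P - |R2_A - R2_P| + coeff * (IIC_C or CII_C)

so the passive training set guards against overtraining and the
calibration set supplies the ideality/intensity term.  Validation
endpoints never enter any accepted move.  The returned model is the
best-TF state seen anywhere along the trajectory.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem_graph import AttributeKey, AttributeKind, featurize
from .data_io import Compound, Dataset, SplitAssignment
from .errors import DegenerateDescriptorError, InvariantError, ZeroVarianceError
from .metrics import cii, iic, target_function

__all__ = [
    "OptimizerConfig",
    "CorrelationWeights",
    "TrainedModel",
    "classify_attributes",
    "dcw",
    "fit_line",
    "optimize",
    "predict",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the Monte Carlo engine.

    ``threshold_t``: minimum number of active-training compounds an
    attribute must occur in to receive a weight (default 3).
    ``epochs_n``: full passes over the active attributes (default 15).
    ``tf_kind``: which calibration index enters the target function.
    ``tf_coefficient``: weighting of that index (default 0.3).
    ``step``: size of the +/- weight perturbation per move.
    ``count_occurrences``: if True, attribute frequency for the T rule
    counts total occurrences instead of compounds containing it.
    """

    threshold_t: int = 3
    epochs_n: int = 15
    tf_kind: str = "cii"  # "iic" or "cii"
    tf_coefficient: float = 0.3
    step: float = 0.1
    init_low: float = 0.5
    init_high: float = 1.5
    seed: int = 0
    count_occurrences: bool = False

    def __post_init__(self):
        if self.threshold_t < 1:
            raise InvariantError("threshold_t must be >= 1")
        if self.epochs_n < 1:
            raise InvariantError("epochs_n must be >= 1")
        if self.step <= 0:
            raise InvariantError("step must be > 0")
        if self.tf_kind not in ("iic", "cii"):
            raise InvariantError(f"unknown tf_kind {self.tf_kind!r}")


@dataclass
class CorrelationWeights:
    weights: dict[AttributeKey, float]
    blocked: frozenset[AttributeKey]

    def __post_init__(self):
        overlap = set(self.weights) & set(self.blocked)
        if overlap:
            raise InvariantError(f"blocked attributes carry weights: {sorted(overlap)[:3]}")

    def get(self, key: AttributeKey) -> float:
        return self.weights.get(key, 0.0)


@dataclass
class TrainedModel:
    cw: CorrelationWeights
    c0: float
    c1: float
    config: OptimizerConfig
    split_fingerprint: str
    tf_trace: list[float] = field(default_factory=list)
    tf_best: float = float("-inf")

    # -- persistence -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "c0": self.c0,
            "c1": self.c1,
            "T": self.config.threshold_t,
            "N": self.config.epochs_n,
            "tf_kind": self.config.tf_kind,
            "tf_coefficient": self.config.tf_coefficient,
            "step": self.config.step,
            "init_low": self.config.init_low,
            "init_high": self.config.init_high,
            "seed": self.config.seed,
            "count_occurrences": self.config.count_occurrences,
            "weights": {
                f"{k.kind.value}|{k.code}": v for k, v in sorted(self.cw.weights.items())
            },
            "blocked": [f"{k.kind.value}|{k.code}" for k in sorted(self.cw.blocked)],
            "split_fingerprint": self.split_fingerprint,
            "tf_trace": self.tf_trace,
            "tf_best": self.tf_best,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)

        def _key(s: str) -> AttributeKey:
            kind, code = s.split("|", 1)
            return AttributeKey(AttributeKind(kind), code)

        cfg = OptimizerConfig(
            threshold_t=d["T"],
            epochs_n=d["N"],
            tf_kind=d["tf_kind"],
            tf_coefficient=d["tf_coefficient"],
            step=d["step"],
            init_low=d["init_low"],
            init_high=d["init_high"],
            seed=d["seed"],
            count_occurrences=d["count_occurrences"],
        )
        cw = CorrelationWeights(
            weights={_key(k): v for k, v in d["weights"].items()},
            blocked=frozenset(_key(k) for k in d["blocked"]),
        )
        return cls(
            cw=cw,
            c0=d["c0"],
            c1=d["c1"],
            config=cfg,
            split_fingerprint=d["split_fingerprint"],
            tf_trace=list(d["tf_trace"]),
            tf_best=d["tf_best"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


def classify_attributes(
    features: Mapping[str, Counter],
    split: SplitAssignment,
    threshold_t: int,
    count_occurrences: bool = False,
) -> tuple[set[AttributeKey], set[AttributeKey]]:
    """Partition attributes into active and rare (blocked) by the T rule.

    Frequency is, by default, the number of active-training compounds
    containing the attribute.  Attributes absent from the active training
    set but present elsewhere are blocked.
    """
    a_ids = split.ids_with_role("A")
    if not a_ids:
        raise InvariantError("empty active training set")
    freq: Counter = Counter()
    for cid in a_ids:
        attrs = features[cid]
        if count_occurrences:
            freq.update(attrs)
        else:
            freq.update(set(attrs))
    all_keys: set[AttributeKey] = set()
    for attrs in features.values():
        all_keys.update(attrs)
    active = {k for k in all_keys if freq.get(k, 0) >= threshold_t}
    return active, all_keys - active


def dcw(attrs: Counter, cw: CorrelationWeights | Mapping[AttributeKey, float]) -> float:
    """Descriptor value: sum of count * weight over the attribute multiset.

    Blocked and unknown attributes contribute 0.
    """
    get = cw.get if isinstance(cw, CorrelationWeights) else lambda k: cw.get(k, 0.0)
    return float(sum(count * get(key) for key, count in attrs.items()))


def fit_line(endpoints, dcws) -> tuple[float, float]:
    """OLS fit of endpoint on DCW over the active training set."""
    y = np.asarray(endpoints, dtype=float)
    x = np.asarray(dcws, dtype=float)
    if len(x) < 2:
        raise DegenerateDescriptorError("need at least 2 points to fit a line")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 1e-14 * len(x):
        raise DegenerateDescriptorError("degenerate descriptor: zero DCW variance")
    c1 = float(xc @ (y - y.mean())) / sxx
    c0 = float(y.mean() - c1 * x.mean())
    return c0, c1


def _r2_fast(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = float(xc @ xc) * float(yc @ yc)
    if den <= 1e-28:
        raise ZeroVarianceError("zero variance")
    return float(xc @ yc) ** 2 / den


def optimize(
    ds: Dataset, split: SplitAssignment, config: OptimizerConfig
) -> TrainedModel:
    """Run the Monte Carlo correlation-weight optimization.

    Deterministic given (dataset, split, config).  Raises if any of the
    A/P/C sets is empty; the validation set is only ever featurized,
    its endpoints are never read.
    """
    features = {c.id: featurize(c.smiles) for c in ds}
    roles = {r: [] for r in "APCV"}
    for i, c in enumerate(ds):
        roles[split.role[c.id]].append(i)
    for r in "APC":
        if not roles[r]:
            raise InvariantError(f"empty {r} set: target function undefined")

    active, blocked = classify_attributes(
        features, split, config.threshold_t, config.count_occurrences
    )
    attrs = sorted(active)
    if not attrs:
        raise DegenerateDescriptorError("no active attributes at this threshold")
    n_attr = len(attrs)

    ids = [c.id for c in ds]
    y_all = np.array([c.endpoint for c in ds], dtype=float)
    idx_a = np.array(roles["A"], dtype=int)
    idx_p = np.array(roles["P"], dtype=int)
    idx_c = np.array(roles["C"], dtype=int)
    y_a, y_p, y_c = y_all[idx_a], y_all[idx_p], y_all[idx_c]

    # sparse incidence: which compounds contain each attribute, with counts
    incidence: list[tuple[np.ndarray, np.ndarray]] = []
    for key in attrs:
        rows, cnts = [], []
        for i, cid in enumerate(ids):
            c = features[cid].get(key, 0)
            if c:
                rows.append(i)
                cnts.append(float(c))
        incidence.append((np.array(rows, dtype=int), np.array(cnts)))

    rng = np.random.default_rng(config.seed)
    weights = rng.uniform(config.init_low, config.init_high, n_attr)
    dcw_vec = np.zeros(len(ds))
    for (rows, cnts), w in zip(incidence, weights):
        dcw_vec[rows] += w * cnts

    index_fn = iic if config.tf_kind == "iic" else cii

    def evaluate(vec: np.ndarray) -> tuple[float, float, float]:
        """TF, c0, c1 of a candidate DCW vector; -inf on degeneracy."""
        try:
            c0, c1 = fit_line(y_a, vec[idx_a])
            r2a = _r2_fast(vec[idx_a], y_a)
            r2p = _r2_fast(vec[idx_p], y_p)
            calc_c = c0 + c1 * vec[idx_c]
            index_c = index_fn(y_c, calc_c)
        except (DegenerateDescriptorError, ZeroVarianceError, ValueError):
            return float("-inf"), 0.0, 0.0
        return (
            target_function(r2a, r2p, index_c, config.tf_coefficient),
            c0,
            c1,
        )

    tf_cur, c0_cur, c1_cur = evaluate(dcw_vec)
    best = (tf_cur, weights.copy(), c0_cur, c1_cur)
    tf_trace: list[float] = []

    step = config.step
    for _epoch in range(config.epochs_n):
        order = rng.permutation(n_attr)
        for j in order:
            rows, cnts = incidence[j]
            best_local = (tf_cur, 0.0, c0_cur, c1_cur)
            for delta in (step, -step):
                cand = dcw_vec.copy()
                cand[rows] += delta * cnts
                tf_new, c0_new, c1_new = evaluate(cand)
                if tf_new > best_local[0]:
                    best_local = (tf_new, delta, c0_new, c1_new)
            tf_cur, delta, c0_cur, c1_cur = best_local
            if delta:
                weights[j] += delta
                dcw_vec[rows] += delta * cnts
            if tf_cur > best[0]:
                best = (tf_cur, weights.copy(), c0_cur, c1_cur)
        tf_trace.append(best[0])

    tf_best, w_best, c0_best, c1_best = best
    cw = CorrelationWeights(
        weights={k: float(w) for k, w in zip(attrs, w_best)},
        blocked=frozenset(blocked),
    )
    return TrainedModel(
        cw=cw,
        c0=c0_best,
        c1=c1_best,
        config=config,
        split_fingerprint=split.fingerprint(),
        tf_trace=tf_trace,
        tf_best=tf_best,
    )


def predict(model: TrainedModel, compounds: Sequence[Compound] | Sequence[str]) -> np.ndarray:
    """Predict endpoints; unseen attributes contribute 0 to the DCW."""
    out = []
    for c in compounds:
        smiles = c.smiles if isinstance(c, Compound) else c
        out.append(model.c0 + model.c1 * dcw(featurize(smiles), model.cw))
    return np.asarray(out)


def multi_seed_configs(config: OptimizerConfig, seeds: Sequence[int]) -> list[OptimizerConfig]:
    return [replace(config, seed=int(s)) for s in seeds]
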