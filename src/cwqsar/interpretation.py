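"""Multi-run mechanistic interpretation.

Running the Monte Carlo optimization several times from different random
starts gives several weight tables.  Attributes whose correlation weight
keeps a strictly positive sign in every run are read as promoters of
endpoint increase; strictly negative in every run, promoters of decrease;
anything mixed (or touching zero) is left undefined.  Sign stability — not
weight magnitude — is the interpretable signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .applicability import AttributeStats, attribute_defect, attribute_stats
from .chem_graph import AttributeKey, featurize
from .data_io import Dataset, SplitAssignment
from .errors import InvariantError
from .optimizer import OptimizerConfig, TrainedModel, optimize

__all__ = ["PromoterRecord", "multi_run", "classify_promoters", "promoter_table", "planted_signal_check"]


@dataclass
class PromoterRecord:
    attribute: AttributeKey
    cw_per_run: list[float]
    classification: str  # "increase" | "decrease" | "undefined"
    freq_a: int
    freq_p: int
    freq_c: int
    defect: float


def multi_run(
    ds: Dataset,
    split: SplitAssignment,
    config: OptimizerConfig,
    seeds: Sequence[int],
) -> list[TrainedModel]:
    """Independent optimizations differing only in their seed."""
    if len(seeds) < 2:
        raise InvariantError("need at least 2 runs for sign-stability analysis")
    if len(set(seeds)) != len(seeds):
        raise InvariantError("seeds must be distinct")
    return [optimize(ds, split, replace(config, seed=int(s))) for s in seeds]


def classify_promoters(
    models: Sequence[TrainedModel],
    stats: Mapping[AttributeKey, AttributeStats],
    min_abs_cw: float = 0.0,
) -> list[PromoterRecord]:
    """Sign-stability classification of every active attribute.

    increase: cw > min_abs_cw in all runs; decrease: cw < -min_abs_cw in
    all runs; otherwise undefined.  Records are sorted by active-training
    frequency descending (ties by attribute code), blocked attributes
    excluded.  Order of the input models does not matter.
    """
    if len(models) < 2:
        raise InvariantError("need at least 2 models")
    keysets = [set(m.cw.weights) for m in models]
    common = set.intersection(*keysets)
    if any(ks != common for ks in keysets):
        raise InvariantError("models do not share one active attribute set")
    records = []
    for key in sorted(common):
        cws = [m.cw.weights[key] for m in models]
        if all(w > min_abs_cw for w in cws):
            cls = "increase"
        elif all(w < -min_abs_cw for w in cws):
            cls = "decrease"
        else:
            cls = "undefined"
        st = stats.get(key)
        records.append(
            PromoterRecord(
                attribute=key,
                cw_per_run=cws,
                classification=cls,
                freq_a=st.freq_a if st else 0,
                freq_p=st.freq_p if st else 0,
                freq_c=st.freq_c if st else 0,
                defect=attribute_defect(st) if st else 0.0,
            )
        )
    records.sort(key=lambda r: (-r.freq_a, r.attribute.code))
    return records


def promoter_table(records: Sequence[PromoterRecord]) -> pd.DataFrame:
    """Promoter report: one row per attribute, defects to 4 decimals."""
    rows = []
    for r in records:
        row = {"attribute": r.attribute.code, "classification": r.classification}
        for i, w in enumerate(r.cw_per_run, start=1):
            row[f"run_{i}"] = round(w, 4)
        row.update(
            {
                "freq_A": r.freq_a,
                "freq_P": r.freq_p,
                "freq_C": r.freq_c,
                "statistical_defect": round(r.defect, 4),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def planted_signal_check(
    ds: Dataset,
    split: SplitAssignment,
    config: OptimizerConfig,
    true_weights: Mapping[AttributeKey, float],
    seeds: Sequence[int] = (11, 12, 13),
) -> dict:
    """Validation harness: do planted effects come back with the right sign?

    Runs the optimizer once per seed, classifies promoters, and reports for
    each planted attribute whether its classification matches the sign of
    its ground-truth weight (attributes blocked by the T rule are skipped).
    """
    models = multi_run(ds, split, config, seeds)
    features = {c.id: featurize(c.smiles) for c in ds}
    stats = attribute_stats(features, split)
    records = {r.attribute: r for r in classify_promoters(models, stats)}
    outcome = {}
    for key, w in true_weights.items():
        rec = records.get(key)
        if rec is None:
            outcome[key.code] = "blocked"
        else:
            expected = "increase" if w > 0 else "decrease" if w < 0 else "undefined"
            outcome[key.code] = "correct" if rec.classification == expected else rec.classification
    n_planted = len(true_weights)
    n_correct = sum(1 for v in outcome.values() if v == "correct")
    return {
        "per_attribute": outcome,
        "n_planted": n_planted,
        "n_correct": n_correct,
        "n_sign_stable_total": sum(
            1 for r in records.values() if r.classification != "undefined"
        ),
        "n_active_total": len(records),
    }
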