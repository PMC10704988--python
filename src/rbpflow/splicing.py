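"""Junction-based splicing ratios and differential event testing.

Each alternative-splicing event carries per-sample junction read counts
supporting the canonical (model) and alternative isoforms.  The
per-sample splicing ratio is alt / (alt + model), masked below a minimum
junction depth.  Events are tested between condition groups with an
unpaired two-tailed Student t-test on the ratios, with Benjamini-Hochberg
control at 5% FDR across testable events.  The t statistic is oriented
knockdown - control, so a positive value means the alternative isoform is
used more after knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .integrate import bh_fdr

EVENT_TYPES = (
    "cassetteExon", "ES", "MXE", "A5SS", "A3SS",
    "A5SS&ES", "A3SS&ES", "5pMXE", "3pMXE",
)

CONTROL, KNOCKDOWN = "control", "knockdown"


@dataclass
class ASEventRecord:
    """One event with per-sample model/alternative junction counts."""

    event_id: str
    gene_id: str
    event_type: str
    model_counts: dict[str, int]
    alt_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event {self.event_id}: unknown event_type {self.event_type!r}"
            )
        if set(self.model_counts) != set(self.alt_counts):
            raise ValueError(
                f"event {self.event_id}: sample sets differ between counts"
            )
        for d in (self.model_counts, self.alt_counts):
            if any(v < 0 for v in d.values()):
                raise ValueError(f"event {self.event_id}: negative counts")


@dataclass
class ASTestResult:
    event_id: str
    gene_id: str
    event_type: str
    mean_ratio_control: float | None
    mean_ratio_knockdown: float | None
    t_value: float | None
    p_value: float | None
    bh_adjusted_p: float | None = None
    significant: bool = False


def splicing_ratio(alt: int, model: int, min_total: int = 10) -> float | None:
    """alt / (alt + model), or None when total junction depth < *min_total*."""
    if alt < 0 or model < 0:
        raise ValueError("counts must be non-negative")
    total = alt + model
    if total < min_total:
        return None
    return alt / total


def _ttest(kd: np.ndarray, ctrl: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sided t-test, oriented knockdown - control.

    Degenerate zero-variance inputs are resolved by the limit: equal means
    give t = 0, p = 1; unequal means give t = +/-inf, p = 0.
    """
    if np.var(kd, ddof=1) == 0 and np.var(ctrl, ddof=1) == 0:
        if kd.mean() == ctrl.mean():
            return 0.0, 1.0
        return float(np.sign(kd.mean() - ctrl.mean()) * np.inf), 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical ratio vectors trip a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(kd, ctrl, equal_var=True)
    return float(t), float(p)


def differential_asevents(
    events: Sequence[ASEventRecord],
    groups: Mapping[str, str],
    alpha_fdr: float = 0.05,
    min_total: int = 10,
    equal_var: bool = True,
) -> list[ASTestResult]:
    """Test every event for a splicing-ratio difference between groups.

    *groups* maps sample -> {control, knockdown}.  Events with fewer than
    two unmasked samples in either group are reported untestable
    (p = None) and excluded from the BH correction.
    """
    results: list[ASTestResult] = []
    testable_idx: list[int] = []
    pvals: list[float] = []
    for ev in events:
        ratios = {
            s: splicing_ratio(ev.alt_counts[s], ev.model_counts[s], min_total)
            for s in ev.model_counts
        }
        ctrl = np.array(
            [r for s, r in ratios.items()
             if groups.get(s) == CONTROL and r is not None]
        )
        kd = np.array(
            [r for s, r in ratios.items()
             if groups.get(s) == KNOCKDOWN and r is not None]
        )
        res = ASTestResult(
            ev.event_id, ev.gene_id, ev.event_type,
            float(ctrl.mean()) if ctrl.size else None,
            float(kd.mean()) if kd.size else None,
            None, None,
        )
        if ctrl.size >= 2 and kd.size >= 2:
            if equal_var:
                t, p = _ttest(kd, ctrl)
            else:
                t, p = stats.ttest_ind(kd, ctrl, equal_var=False)
                t, p = float(t), float(p)
            res.t_value, res.p_value = t, p
            testable_idx.append(len(results))
            pvals.append(p)
        results.append(res)
    if pvals:
        adj = bh_fdr(np.array(pvals))
        for i, a in zip(testable_idx, adj):
            results[i].bh_adjusted_p = float(a)
            results[i].significant = bool(a <= alpha_fdr)
    return results


def implied_p_cutoff(results: Sequence[ASTestResult]) -> float | None:
    """Largest raw p among significant events: the p cutoff the BH rule implies."""
    sig = [r.p_value for r in results if r.significant and r.p_value is not None]
    return max(sig) if sig else None


def classify_event_direction(results: Sequence[ASTestResult]) -> pd.DataFrame:
    """Count significant events by type and t-sign (increased/decreased).

    "increased" means the alternative isoform's proportion is higher in
    the knockdown group (positive t).
    """
    table = pd.DataFrame(
        0, index=list(EVENT_TYPES), columns=["increased", "decreased"], dtype=int
    )
    for r in results:
        if not r.significant or r.t_value is None or r.t_value == 0:
            continue
        col = "increased" if r.t_value > 0 else "decreased"
        table.loc[r.event_type, col] += 1
    return table


# ---------------------------------------------------------------------------
# TSV I/O: event_id, gene_id, event_type, model_<sample>..., alt_<sample>...
# ---------------------------------------------------------------------------

def read_asevents_tsv(path) -> list[ASEventRecord]:
    df = pd.read_csv(path, sep="\t")
    model_cols = [c for c in df.columns if c.startswith("model_")]
    alt_cols = [c for c in df.columns if c.startswith("alt_")]
    samples = [c[len("model_"):] for c in model_cols]
    if samples != [c[len("alt_"):] for c in alt_cols]:
        raise ValueError("model_/alt_ sample columns do not match")
    events = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        events.append(
            ASEventRecord(
                str(d["event_id"]), str(d["gene_id"]), str(d["event_type"]),
                {s: int(d[f"model_{s}"]) for s in samples},
                {s: int(d[f"alt_{s}"]) for s in samples},
            )
        )
    return events


def write_asresults_tsv(results: Sequence[ASTestResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
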