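"""Reaction-time outlier filtering for dot-probe trials.

Two exclusion rules are applied per subject (and per task when a table mixes
tasks):

* **slow outliers** — RTs above ``median + multiplier * MAD``, with the MAD
  scaled by the normal-consistency constant 1.4826 by default (a raw-MAD
  option is exposed since conventions differ);
* **anticipatory responses** — RTs below a fixed floor (200 ms by default),
  which are too fast to reflect processing of the probe.

Trials excluded in the primary sessions can be re-run in subject-specific
repetition sessions; :func:`merge_repetitions` combines the two filtered
batches, applying the same verdicts to the repetition round, so a trial
excluded in both rounds is lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

__all__ = ["FilterReport", "mad_upper_threshold", "filter_trials", "merge_repetitions"]

#: normal-consistency scaling for the MAD
MAD_SCALE = 1.4826


@dataclass
class FilterReport:
    """Per-batch trial accounting for one subject (or a combined batch)."""

    n_collected: int
    n_excluded_slow: int
    n_excluded_fast: int
    threshold_ms: float = float("nan")
    unfilterable: bool = False

    @classmethod
    def from_totals(cls, n_collected: int, n_excluded: int) -> "FilterReport":
        """Build a report from total counts when the slow/fast split is unknown.

        Published trial accounting typically reports only how many trials
        were excluded in total; the split is booked as slow here since it
        does not affect retained counts or exclusion percentages.
        """
        return cls(n_collected=n_collected, n_excluded_slow=n_excluded, n_excluded_fast=0)

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_slow + self.n_excluded_fast

    @property
    def n_retained(self) -> int:
        return self.n_collected - self.n_excluded

    @property
    def exclusion_pct(self) -> float:
        """Excluded share of collected trials, in percent."""
        if self.n_collected == 0:
            return 0.0
        return 100.0 * self.n_excluded / self.n_collected

    def __add__(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            n_collected=self.n_collected + other.n_collected,
            n_excluded_slow=self.n_excluded_slow + other.n_excluded_slow,
            n_excluded_fast=self.n_excluded_fast + other.n_excluded_fast,
            threshold_ms=float("nan"),
            unfilterable=self.unfilterable or other.unfilterable,
        )


def mad_upper_threshold(rts, multiplier: float = 2.5, scaled: bool = True) -> float:
    """Upper RT limit ``median + multiplier * MAD``.

    Parameters
    ----------
    rts : array-like of RTs in ms; at least two finite values required.
    multiplier : MAD multiplier (2.5 is the conventional moderately
        conservative choice).
    scaled : if True (default) the MAD carries the 1.4826 normal-consistency
        factor; if False the raw median absolute deviation is used.
    """
    arr = np.asarray(rts, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 finite RTs to form a MAD threshold")
    med = float(np.median(arr))
    mad = float(median_abs_deviation(arr, scale="normal" if scaled else 1.0))
    return med + multiplier * mad


def filter_trials(
    trials: pd.DataFrame,
    floor_ms: float = 200.0,
    multiplier: float = 2.5,
    scaled_mad: bool = True,
    fast_first: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Partition trials into retained and excluded by the two RT rules.

    Thresholds are computed per subject x task on all trials of the submitted
    batch.  With ``fast_first=True`` the sub-floor trials are removed before
    the MAD threshold is computed (the default computes it on the full batch).

    Returns ``(retained, excluded, reports)`` where ``excluded`` carries an
    ``exclusion_reason`` column (``"slow"`` / ``"fast"``) and ``reports`` maps
    ``(subject_id, task)`` to a :class:`FilterReport`.  A subject x task group
    with fewer than two trials cannot support a MAD threshold; its trials are
    passed through retained and the report is flagged ``unfilterable``.
    """
    if trials.empty:
        empty = trials.copy()
        excluded = trials.copy()
        excluded["exclusion_reason"] = pd.Series(dtype=object)
        return empty, excluded, {}

    retained_parts, excluded_parts, reports = [], [], {}
    group_cols = ["subject_id", "task"] if "task" in trials.columns else ["subject_id"]
    for key, grp in trials.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rts = grp["rt_ms"].to_numpy(dtype=float)
        if len(grp) < 2:
            reports[key] = FilterReport(len(grp), 0, 0, unfilterable=True)
            retained_parts.append(grp)
            continue
        if fast_first:
            basis = rts[rts >= floor_ms]
            if basis.size < 2:
                reports[key] = FilterReport(len(grp), 0, 0, unfilterable=True)
                retained_parts.append(grp)
                continue
        else:
            basis = rts
        thr = mad_upper_threshold(basis, multiplier=multiplier, scaled=scaled_mad)
        fast = rts < floor_ms
        slow = ~fast & (rts > thr)
        keep = ~fast & ~slow
        reports[key] = FilterReport(
            n_collected=len(grp),
            n_excluded_slow=int(slow.sum()),
            n_excluded_fast=int(fast.sum()),
            threshold_ms=thr,
        )
        retained_parts.append(grp.loc[keep])
        exc = grp.loc[~keep].copy()
        exc["exclusion_reason"] = np.where(fast[~keep], "fast", "slow")
        excluded_parts.append(exc)

    retained = pd.concat(retained_parts) if retained_parts else trials.iloc[0:0]
    if excluded_parts:
        excluded = pd.concat(excluded_parts)
    else:
        excluded = trials.iloc[0:0].copy()
        excluded["exclusion_reason"] = pd.Series(dtype=object)
    return retained.sort_index(), excluded.sort_index(), reports


_MATCH_COLS = ["subject_id", "pair_id", "congruence"]


def merge_repetitions(
    primary: tuple[pd.DataFrame, pd.DataFrame, dict],
    repetition: tuple[pd.DataFrame, pd.DataFrame, dict],
) -> tuple[pd.DataFrame, dict]:
    """Combine a primary filtered batch with its repetition round.

    The final table is the union of the two retained sets; trials excluded in
    both rounds are dropped.  Reports are summed per subject x task.  A
    repetition trial whose (subject, pair, congruence) does not match any
    excluded primary trial triggers a warning but still enters the final
    table according to its own filter verdict.
    """
    p_ret, p_exc, p_rep = primary
    r_ret, r_exc, r_rep = repetition

    if not r_ret.empty and all(c in p_exc.columns for c in _MATCH_COLS):
        rep_all = pd.concat([r_ret, r_exc]) if not r_exc.empty else r_ret
        exc_keys = set(map(tuple, p_exc[_MATCH_COLS].to_numpy())) if not p_exc.empty else set()
        rep_keys = set(map(tuple, rep_all[_MATCH_COLS].to_numpy()))
        orphans = rep_keys - exc_keys
        if orphans:
            warnings.warn(
                f"{len(orphans)} repetition trial key(s) have no matching excluded "
                "primary trial; they are kept per their own filter verdict",
                stacklevel=2,
            )

    final = pd.concat([p_ret, r_ret]) if not r_ret.empty else p_ret.copy()
    combined: dict = {}
    for key in set(p_rep) | set(r_rep):
        zero = FilterReport(0, 0, 0)
        combined[key] = p_rep.get(key, zero) + r_rep.get(key, zero)
    return final, combined
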