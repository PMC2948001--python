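"""Patient metadata: response labelling, RNA-quality filtering, cohort summaries.

The clinical setting is paediatric acute severe ulcerative colitis treated with
intravenous corticosteroids. Disease activity is scored by the Pediatric
Ulcerative Colitis Activity Index (PUCAI, 0-85). A patient counts as a
*responder* when no second-line medical therapy or surgery was needed and the
day-5 PUCAI is at or below 45; everyone else is a *non-responder*
(corticosteroid-resistant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

PUCAI_MIN, PUCAI_MAX = 0, 85

#: Day-5 PUCAI at or below this score (without second-line therapy) = response.
PUCAI_RESPONSE_CUTOFF = 45

#: Samples need an RNA Integrity Number strictly above this to enter analysis.
RIN_THRESHOLD = 5.5


class LabelingError(ValueError):
    """Response label cannot be derived from the available fields."""


@dataclass(frozen=True)
class SampleRecord:
    """One patient's metadata row.

    ``response_label`` is derived, not measured: it is absent until
    :func:`classify_response` has been applied.
    """

    sample_id: str
    batch_id: int
    sex: str
    age: float
    disease_duration: float | None
    pucai_day1: int | None
    pucai_day3: int | None
    pucai_day5: int | None
    second_line_or_surgery: bool
    rin: float
    response_label: str | None = None

    def __post_init__(self):
        if self.batch_id not in (1, 2):
            raise ValueError(f"batch_id must be 1 or 2, got {self.batch_id}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("pucai_day1", "pucai_day3", "pucai_day5"):
            value = getattr(self, name)
            if value is not None and not (PUCAI_MIN <= value <= PUCAI_MAX):
                raise ValueError(f"{name}={value} outside [{PUCAI_MIN}, {PUCAI_MAX}]")
        if not (0.0 <= self.rin <= 10.0):
            raise ValueError(f"rin={self.rin} outside [0, 10]")
        if self.response_label not in (None, RESPONDER, NON_RESPONDER):
            raise ValueError(f"unknown response_label {self.response_label!r}")


def classify_response(record: SampleRecord) -> SampleRecord:
    """Return a copy of ``record`` with the derived response label.

    Responder iff no second-line therapy/surgery AND day-5 PUCAI <= 45.
    A patient who went to second-line therapy is a non-responder regardless of
    any PUCAI score; otherwise the day-5 score is required.
    """
    if record.second_line_or_surgery:
        return replace(record, response_label=NON_RESPONDER)
    if record.pucai_day5 is None:
        raise LabelingError(
            f"sample {record.sample_id}: no second-line therapy and no day-5 PUCAI; "
            "cannot decide response"
        )
    label = RESPONDER if record.pucai_day5 <= PUCAI_RESPONSE_CUTOFF else NON_RESPONDER
    return replace(record, response_label=label)


def qc_filter_rin(
    records: Sequence[SampleRecord], threshold: float = RIN_THRESHOLD
) -> list[SampleRecord]:
    """Keep records with RIN strictly greater than ``threshold``, order preserved."""
    return [r for r in records if r.rin > threshold]


# ---------------------------------------------------------------------------
# Table-1-style summaries
# ---------------------------------------------------------------------------

#: (field, display name, decimals for display)
_NUMERIC_FIELDS = (
    ("age", "Age", 1),
    ("disease_duration", "Disease Duration (mon.)", 0),
    ("pucai_day1", "PUCAI Day 1", 0),
    ("pucai_day3", "PUCAI Day 3", 0),
    ("pucai_day5", "PUCAI Day 5", 0),
)


def round_display(x: float, decimals: int) -> float:
    """Decimal half-up rounding for display, after clearing float dust.

    The table convention rounds 13.55 -> 13.6; binary floats represent such
    means as 13.549999..., so the value is first rounded well below display
    precision and then quantized half-up.
    """
    from decimal import ROUND_HALF_UP, Decimal

    if math.isnan(x):
        return x
    cleaned = Decimal(repr(round(x, decimals + 6)))
    quantum = Decimal(1).scaleb(-decimals)
    return float(cleaned.quantize(quantum, rounding=ROUND_HALF_UP))


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    sd = arr.std(ddof=1) if arr.size > 1 else math.nan
    return float(arr.mean()), float(sd)


def _stratum_rows(
    label: str, responders: list[SampleRecord], non_responders: list[SampleRecord],
    with_pvalues: bool,
) -> list[dict]:
    rows = [
        {
            "stratum": label, "field": "N",
            "responder": float(len(responders)), "non_responder": float(len(non_responders)),
            "responder_sd": math.nan, "non_responder_sd": math.nan,
            "n_responder": len(responders), "n_non_responder": len(non_responders),
            "p_value": math.nan, "test": "",
        }
    ]
    r_m = sum(1 for r in responders if r.sex == "male")
    n_m = sum(1 for r in non_responders if r.sex == "male")
    sex_row = {
        "stratum": label, "field": "Male/Female",
        "responder": float(r_m), "non_responder": float(n_m),
        "responder_sd": float(len(responders) - r_m),
        "non_responder_sd": float(len(non_responders) - n_m),
        "n_responder": len(responders), "n_non_responder": len(non_responders),
        "p_value": math.nan, "test": "",
    }
    if with_pvalues and responders and non_responders:
        table = [[r_m, len(responders) - r_m], [n_m, len(non_responders) - n_m]]
        sex_row["p_value"] = float(stats.fisher_exact(table)[1])
        sex_row["test"] = "fisher_exact (method not stated in source table)"
    rows.append(sex_row)

    for field_name, display, _ in _NUMERIC_FIELDS:
        r_vals = [getattr(r, field_name) for r in responders if getattr(r, field_name) is not None]
        n_vals = [getattr(r, field_name) for r in non_responders if getattr(r, field_name) is not None]
        r_mean, r_sd = _mean_sd(r_vals)
        n_mean, n_sd = _mean_sd(n_vals)
        row = {
            "stratum": label, "field": display,
            "responder": r_mean, "non_responder": n_mean,
            "responder_sd": r_sd, "non_responder_sd": n_sd,
            "n_responder": len(r_vals), "n_non_responder": len(n_vals),
            "p_value": math.nan, "test": "",
        }
        if with_pvalues and len(r_vals) > 1 and len(n_vals) > 1:
            row["p_value"] = float(stats.ttest_ind(r_vals, n_vals, equal_var=False).pvalue)
            row["test"] = "welch_t (method not stated in source table)"
        rows.append(row)
    return rows


def summarize_cohort(
    records: Sequence[SampleRecord],
    grouping: str = "per_batch",
    with_pvalues: bool = True,
) -> pd.DataFrame:
    """Batch-wise and/or combined characteristics table, one row per field.

    ``grouping``: ``"per_batch"`` (one stratum per batch), ``"combined"``
    (single stratum), or ``"both"``. Means and SDs are returned at full
    precision; :func:`format_summary` applies the display rounding
    (one decimal for age, integers for PUCAI and duration).
    """
    if grouping not in ("per_batch", "combined", "both"):
        raise ValueError(f"unknown grouping {grouping!r}")
    unlabeled = [r.sample_id for r in records if r.response_label is None]
    if unlabeled:
        raise LabelingError(f"records not labeled: {unlabeled[:5]}")

    strata: list[tuple[str, list[SampleRecord]]] = []
    if grouping in ("per_batch", "both"):
        for batch in sorted({r.batch_id for r in records}):
            strata.append((f"Batch {batch}", [r for r in records if r.batch_id == batch]))
    if grouping in ("combined", "both"):
        strata.append(("Combined", list(records)))

    rows: list[dict] = []
    for label, members in strata:
        if not members:
            import warnings

            warnings.warn(f"stratum {label!r} is empty; omitted", stacklevel=2)
            continue
        responders = [r for r in members if r.response_label == RESPONDER]
        non_responders = [r for r in members if r.response_label == NON_RESPONDER]
        rows.extend(_stratum_rows(label, responders, non_responders, with_pvalues))
    return pd.DataFrame(rows)


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a :func:`summarize_cohort` frame as display strings (table rounding)."""
    decimals = {display: nd for _, display, nd in _NUMERIC_FIELDS}
    out_rows = []
    for _, row in summary.iterrows():
        field = row["field"]
        if field == "N":
            fmt = lambda m, s: f"{int(m)}"
        elif field == "Male/Female":
            fmt = lambda m, s: f"{int(m)}/{int(s)}"
        else:
            nd = decimals.get(field, 1)
            fmt = lambda m, s, nd=nd: (
                f"{round_display(m, nd):.{nd}f}±{round_display(s, nd):.{nd}f}"
                if not math.isnan(m)
                else "-"
            )
        out_rows.append(
            {
                "stratum": row["stratum"],
                "field": field,
                "responder": fmt(row["responder"], row["responder_sd"]),
                "non_responder": fmt(row["non_responder"], row["non_responder_sd"]),
                "p_value": "-" if math.isnan(row["p_value"]) else f"{row['p_value']:.4f}",
                "test": row["test"],
            }
        )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Metadata I/O (tab-separated text)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "sample_id", "batch_id", "sex", "age", "disease_duration",
    "pucai_day1", "pucai_day3", "pucai_day5", "second_line_or_surgery",
    "rin", "response_label",
]


def write_metadata(records: Iterable[SampleRecord], path) -> None:
    frame = pd.DataFrame([vars(r) for r in records], columns=_COLUMNS)
    frame["second_line_or_surgery"] = frame["second_line_or_surgery"].map(
        {True: "true", False: "false"}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    records = []
    for _, row in frame.iterrows():
        def _opt_int(v):
            return None if pd.isna(v) else int(v)

        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                batch_id=int(row["batch_id"]),
                sex=row["sex"],
                age=float(row["age"]),
                disease_duration=None
                if pd.isna(row.get("disease_duration"))
                else float(row["disease_duration"]),
                pucai_day1=_opt_int(row.get("pucai_day1")),
                pucai_day3=_opt_int(row.get("pucai_day3")),
                pucai_day5=_opt_int(row.get("pucai_day5")),
                second_line_or_surgery=str(row["second_line_or_surgery"]).lower() == "true",
                rin=float(row["rin"]),
                response_label=None
                if pd.isna(row.get("response_label"))
                else row["response_label"],
            )
        )
    return records
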