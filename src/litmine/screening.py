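"""Manual abstract-screening records and the include/exclude flow tallies.

Screening of scraped articles against a fixed exclusion taxonomy: each
excluded article carries one or more reasons (reasons may overlap — an
article can be both an animal study and a non-primary article), included
articles carry none. The tally reports exact counts and the exclusion
percentage to one decimal (half-up rounding), mirroring the flow-diagram
arithmetic n_excluded = n_scraped - n_included.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

logger = logging.getLogger(__name__)

#: The frozen exclusion-reason vocabulary (extensible via `extra_reasons`).
REASON_CODES = (
    "review_commentary_protocol_lecture",
    "animal_study",
    "not_related",
    "non_primary",
    "non_english",
    "systematic_review_meta",
    "no_abstract_access",
)


@dataclass
class ScreeningRecord:
    article_id: str
    decision: str  # included | excluded
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.decision not in ("included", "excluded"):
            raise ValueError(f"invalid decision {self.decision!r}")
        if self.decision == "excluded" and not self.reasons:
            raise ValueError(
                f"article {self.article_id}: excluded record must carry >= 1 reason"
            )
        if self.decision == "included" and self.reasons:
            raise ValueError(
                f"article {self.article_id}: included record must carry no reasons"
            )


@dataclass
class FlowTally:
    n_scraped: int
    n_included: int
    n_excluded: int
    pct_excluded: float
    per_reason: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "n_scraped": self.n_scraped,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "pct_excluded": self.pct_excluded,
            "per_reason": self.per_reason,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    def flow_summary(self) -> str:
        """Human-readable flow mirroring the screening diagram's boxes."""
        lines = [
            f"scraped: {self.n_scraped}",
            f"included: {self.n_included}",
            f"excluded: {self.n_excluded} ({self.pct_excluded}%)",
        ]
        for code, n in sorted(self.per_reason.items(), key=lambda kv: -kv[1]):
            lines.append(f"  - {code}: {n}")
        return "\n".join(lines)


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tally(records: Sequence[ScreeningRecord], n_scraped: int) -> FlowTally:
    """Exact flow counts; per-reason counts may exceed n_excluded (overlap).

    Records need not cover every scraped article: articles without a record
    are counted as excluded only through n_scraped - n_included arithmetic
    when all records are included, so in normal use records cover them all.
    """
    if n_scraped < len(records):
        raise ValueError(
            f"n_scraped={n_scraped} < number of screening records {len(records)}"
        )
    n_included = sum(1 for r in records if r.decision == "included")
    n_excluded = n_scraped - n_included
    pct = _round_half_up_1dp(100.0 * n_excluded / n_scraped) if n_scraped else 0.0
    per_reason: dict[str, int] = {}
    for r in records:
        for reason in r.reasons:
            per_reason[reason] = per_reason.get(reason, 0) + 1
    return FlowTally(
        n_scraped=n_scraped,
        n_included=n_included,
        n_excluded=n_excluded,
        pct_excluded=pct,
        per_reason=per_reason,
    )


def read_screening(
    path: str | Path, extra_reasons: Sequence[str] = ()
) -> list[ScreeningRecord]:
    """Read a screening CSV (article_id, decision, reasons ';'-separated).

    Unknown reason codes are a parse error naming the row, unless declared
    in ``extra_reasons`` (logged as an extension of the taxonomy).
    """
    valid = set(REASON_CODES) | set(extra_reasons)
    if extra_reasons:
        logger.warning("screening taxonomy extended with: %s", sorted(extra_reasons))
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"article_id", "decision", "reasons"}
        if reader.fieldnames is None or not need.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: screening CSV must have columns article_id,decision,reasons"
            )
        for i, row in enumerate(reader, start=2):
            decision = (row.get("decision") or "").strip()
            if not decision:
                raise ValueError(f"{path}: row {i}: missing decision")
            reasons = tuple(
                r.strip() for r in (row.get("reasons") or "").split(";") if r.strip()
            )
            unknown = [r for r in reasons if r not in valid]
            if unknown:
                raise ValueError(f"{path}: row {i}: unknown reason code(s) {unknown}")
            try:
                records.append(
                    ScreeningRecord(
                        article_id=(row.get("article_id") or "").strip(),
                        decision=decision,
                        reasons=reasons,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_screening(records: Sequence[ScreeningRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["article_id", "decision", "reasons"])
        for r in records:
            w.writerow([r.article_id, r.decision, ";".join(r.reasons)])
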