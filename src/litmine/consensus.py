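"""Multi-rater topic-label consensus with chance-corrected agreement.

R raters each propose one free-text label per topic. After user-supplied
synonym reconciliation, per-topic consensus is summarised by a
*mode-agreement kappa*: the binary event is "this rater's label equals the
modal label", so observed agreement is p_o = (mode count)/R, chance
agreement is p_e = sum_l q_l^2 over the empirical label frequencies q_l in
the column, and

    kappa = (p_o - p_e) / (1 - p_e).

Two variants: *stringent* uses the single largest mode; *lenient*, for
topics where two labels jointly dominate (bimodal), merges the two modal
labels into one category before the same computation, so lenient >=
stringent on every bimodal topic. Fleiss' multi-rater kappa (via
statsmodels) is reported alongside as the textbook alternative.

Kappa values are interpreted on the conventional bands: <0 no agreement,
0-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial,
0.81-1 almost perfect (half-open at the second decimal).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

__all__ = [
    "RaterTable",
    "ConsensusResult",
    "normalise_labels",
    "topic_modes",
    "kappa_stringent",
    "kappa_lenient",
    "band",
    "evaluate",
]

MISSING = ""

_BANDS = [
    (-np.inf, 0.0, "no agreement"),
    (0.0, 0.205, "slight"),
    (0.205, 0.405, "fair"),
    (0.405, 0.605, "moderate"),
    (0.605, 0.805, "substantial"),
    (0.805, np.inf, "almost perfect"),
]


def band(kappa: float) -> str:
    """Interpretation band for a kappa value (cut-points at the 2nd decimal)."""
    if kappa > 1 + 1e-12:
        raise ValueError(f"kappa must be <= 1, got {kappa}")
    for lo, hi, name in _BANDS:
        if lo <= kappa < hi:
            return name
    return "almost perfect"


def _basic_normalise(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip().lower())


@dataclass
class RaterTable:
    """R x T matrix of categorical labels (rows = raters, cols = topics)."""

    labels: pd.DataFrame  # raters x topics, string cells; MISSING marks absent

    def __post_init__(self):
        if self.labels.shape[0] < 2:
            raise ValueError("need at least 2 raters")

    @property
    def n_raters(self) -> int:
        return self.labels.shape[0]

    @property
    def n_topics(self) -> int:
        return self.labels.shape[1]

    def column(self, topic) -> list[str]:
        """Non-missing labels for one topic."""
        col = self.labels[topic].tolist()
        return [c for c in col if c != MISSING]

    @property
    def label_alphabet(self) -> list[str]:
        vals = set(self.labels.values.ravel()) - {MISSING}
        return sorted(vals)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RaterTable":
        df = pd.read_csv(path, dtype=str).fillna(MISSING)
        if df.columns[0].lower() in ("rater", "rater_id"):
            df = df.set_index(df.columns[0])
        return cls(df)


def normalise_labels(
    raw: RaterTable | pd.DataFrame,
    synonym_map: Mapping[str, str] | None = None,
) -> RaterTable:
    """Lowercase, collapse whitespace, then map labels through synonym_map.

    The synonym map is many-to-one (e.g. both "allergy" and "allergies" to
    "allergies"); unmapped labels pass through unchanged. A map whose targets
    are themselves remapped to something different (a chain or cycle) is a
    conflict and raises.
    """
    df = raw.labels if isinstance(raw, RaterTable) else raw
    syn = { _basic_normalise(k): _basic_normalise(v) for k, v in (synonym_map or {}).items() }
    for src, dst in syn.items():
        if dst in syn and syn[dst] != dst:
            raise ValueError(
                f"synonym map conflict: {src!r} -> {dst!r} but {dst!r} -> {syn[dst]!r}"
            )
    def apply(cell: str) -> str:
        if cell == MISSING:
            return MISSING
        norm = _basic_normalise(cell)
        return syn.get(norm, norm)
    return RaterTable(df.map(apply))


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV (variant, canonical) -> mapping."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or (i == 1 and row[0].lower() in ("variant", "from", "label")):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {i}: need 2 columns")
            if row[0] in out and out[row[0]] != row[1]:
                raise ValueError(f"{path}: row {i}: conflicting entry for {row[0]!r}")
            out[row[0]] = row[1]
    return out


def topic_modes(
    column: Sequence[str], near_tie_delta: int = 0
) -> tuple[list[str], list[int], bool]:
    """Modal label(s) of one topic's column and whether it is bimodal.

    Bimodal iff exactly two labels jointly dominate: either an exact tie for
    the top count, or (with ``near_tie_delta`` > 0) a second label within
    delta of the top count. Returns (modes, counts, is_bimodal), modes sorted
    by decreasing count then alphabetically.
    """
    labels = [c for c in column if c != MISSING]
    if not labels:
        raise ValueError("topic unratable: all labels missing")
    counts = pd.Series(labels).value_counts()
    top = int(counts.iloc[0])
    # deterministic order: decreasing count, ties alphabetical
    contenders = sorted(
        ((l, int(c)) for l, c in counts.items() if c >= top - near_tie_delta),
        key=lambda lc: (-lc[1], lc[0]),
    )
    is_bimodal = len(contenders) == 2
    if is_bimodal:
        modes = [l for l, _ in contenders]
        mode_counts = [c for _, c in contenders]
    else:
        modes = sorted(l for l, c in counts.items() if c == top)
        mode_counts = [top] * len(modes)
    return modes, mode_counts, is_bimodal


def _mode_kappa(labels: Sequence[str], mode_set: set[str]) -> float:
    """Chance-corrected agreement with a (possibly merged) modal category."""
    R = len(labels)
    counts = pd.Series(list(labels)).value_counts()
    q = counts / R
    p_o = float(sum(q[l] for l in mode_set if l in q.index))
    p_e = float((q**2).sum())
    if mode_set:
        # merged category: chance agreement uses merged frequencies
        merged_q = p_o
        others = q[~q.index.isin(mode_set)]
        p_e = float(merged_q**2 + (others**2).sum())
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_stringent(column: Sequence[str]) -> tuple[float, str]:
    """Agreement with the single largest mode; ties broken alphabetically."""
    labels = [c for c in column if c != MISSING]
    if len(labels) < 2:
        raise ValueError("need >= 2 non-missing labels")
    modes, _, _ = topic_modes(labels)
    k = _mode_kappa(labels, {modes[0]})
    return k, band(k)


def kappa_lenient(column: Sequence[str], near_tie_delta: int = 0) -> tuple[float, str]:
    """Agreement with either of the two modes on bimodal topics.

    On unimodal topics this equals the stringent statistic exactly.
    """
    labels = [c for c in column if c != MISSING]
    if len(labels) < 2:
        raise ValueError("need >= 2 non-missing labels")
    modes, _, is_bimodal = topic_modes(labels, near_tie_delta)
    if not is_bimodal:
        return kappa_stringent(labels)
    k = _mode_kappa(labels, set(modes[:2]))
    return k, band(k)


def fleiss(table: RaterTable) -> float:
    """Fleiss' multi-rater kappa over the whole table (statsmodels)."""
    arr, _ = aggregate_raters(table.labels.T.values)  # subjects = topics
    return float(fleiss_kappa(arr))


@dataclass
class TopicConsensus:
    topic: str
    modes: list[str]
    mode_counts: list[int]
    is_bimodal: bool
    kappa_stringent: float
    band_stringent: str
    kappa_lenient: float
    band_lenient: str


@dataclass
class ConsensusResult:
    per_topic: list[TopicConsensus]
    fleiss_kappa: float
    band_counts_stringent: dict[str, int] = field(default_factory=dict)
    band_counts_lenient: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "topic": [t.topic for t in self.per_topic],
                "modes": ["|".join(t.modes) for t in self.per_topic],
                "is_bimodal": [t.is_bimodal for t in self.per_topic],
                "kappa_stringent": [t.kappa_stringent for t in self.per_topic],
                "band_stringent": [t.band_stringent for t in self.per_topic],
                "kappa_lenient": [t.kappa_lenient for t in self.per_topic],
                "band_lenient": [t.band_lenient for t in self.per_topic],
            }
        )

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "fleiss_kappa": self.fleiss_kappa,
            "band_counts_stringent": self.band_counts_stringent,
            "band_counts_lenient": self.band_counts_lenient,
            "topics": [
                {
                    "topic": t.topic,
                    "modes": t.modes,
                    "mode_counts": t.mode_counts,
                    "is_bimodal": t.is_bimodal,
                    "kappa_stringent": t.kappa_stringent,
                    "band_stringent": t.band_stringent,
                    "kappa_lenient": t.kappa_lenient,
                    "band_lenient": t.band_lenient,
                }
                for t in self.per_topic
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc


def evaluate(table: RaterTable, near_tie_delta: int = 0) -> ConsensusResult:
    """Full per-topic consensus analysis of a normalised rater table."""
    per_topic = []
    for topic in table.labels.columns:
        col = table.column(topic)
        modes, counts, bim = topic_modes(col, near_tie_delta)
        ks, bs = kappa_stringent(col)
        kl, bl = kappa_lenient(col, near_tie_delta)
        per_topic.append(
            TopicConsensus(
                topic=str(topic),
                modes=modes,
                mode_counts=counts,
                is_bimodal=bim,
                kappa_stringent=ks,
                band_stringent=bs,
                kappa_lenient=kl,
                band_lenient=bl,
            )
        )
    band_s: dict[str, int] = {}
    band_l: dict[str, int] = {}
    for t in per_topic:
        band_s[t.band_stringent] = band_s.get(t.band_stringent, 0) + 1
        band_l[t.band_lenient] = band_l.get(t.band_lenient, 0) + 1
    return ConsensusResult(
        per_topic=per_topic,
        fleiss_kappa=fleiss(table),
        band_counts_stringent=band_s,
        band_counts_lenient=band_l,
    )
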