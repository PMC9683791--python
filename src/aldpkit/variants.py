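"""Disease-variant table parsing and hotspot calling.

A residue is a *hotspot* when the variant catalogue reports substitutions
to two or more distinct amino acids at that position — a purely
count-based definition over distinct alternate residues (not distinct
nucleotide changes). By default only missense variants enter hotspot
calling, because mapping a substitution onto the 3D structure requires a
substituted residue; nonsense and other classes are retained in the
rejects/other report rather than silently dropped.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError
from .structure_model import THREE_TO_ONE

AA1 = set("ACDEFGHIKLMNPQRSTVWY")
NONSENSE_ALTS = {"*", "X", "TER"}

_SHORTHAND = re.compile(
    r"^(?:p\.)?\(?([A-Za-z]{1,3})(\d+)([A-Za-z*]{1,3}|\*)\)?$"
)


@dataclass
class VariantRecord:
    residue_number: int
    ref_aa: str
    alt_aa: str  # 1-letter, or '*' for nonsense
    variant_class: str = "missense"  # missense | nonsense | other
    source_label: str = ""

    def __post_init__(self):
        if self.residue_number < 1:
            raise ValidationError(f"residue_number {self.residue_number} < 1")
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"ref and alt identical at {self.residue_number}: {self.ref_aa}"
            )


@dataclass
class ParseResult:
    records: list[VariantRecord]
    rejects: list[tuple[int, str, str]]  # (row index, raw, reason)
    warning: str | None = None


def _normalize_aa(token: str) -> str | None:
    token = token.strip()
    if not token:
        return None
    upper = token.upper()
    if upper in NONSENSE_ALTS:
        return "*"
    if len(token) == 1:
        return upper if upper in AA1 else None
    return THREE_TO_ONE.get(upper)


def parse_protein_change(text: str) -> tuple[int, str, str]:
    """Parse HGVS-like protein shorthand: ``W339R``, ``p.W339R``,
    ``p.Trp339Arg``, ``p.(Arg104Cys)``, ``W339*``.

    Returns (residue_number, ref_aa, alt_aa) with 1-letter codes
    ('*' for a stop gain). Raises ValidationError on anything else.
    """
    m = _SHORTHAND.match(str(text).strip())
    if not m:
        raise ValidationError(f"unparseable protein change {text!r}")
    ref = _normalize_aa(m.group(1))
    alt = _normalize_aa(m.group(3))
    if ref is None or ref == "*" or alt is None:
        raise ValidationError(f"unknown amino-acid code in {text!r}")
    return int(m.group(2)), ref, alt


DEFAULT_COLUMN_MAP = {"variant": "protein_change", "class": "variant_class",
                      "source": "source"}


def parse_variant_table(
    source: str | Path | pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    filter_classes: Iterable[str] | None = ("missense",),
    sep: str | None = None,
    residue_offset: int = 0,
) -> ParseResult:
    """Parse a delimited variant table into validated records.

    ``column_map`` maps logical -> actual column names. Two shapes are
    accepted: a single ``variant`` column holding protein-change shorthand,
    or explicit ``residue``/``ref``/``alt`` columns. Optional logical
    columns: ``class``, ``source``. Rows failing validation are collected
    in ``rejects`` with a reason, never silently dropped.
    ``residue_offset`` is added to every residue number (numbering-scheme
    reconciliation against the structure).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if isinstance(source, pd.DataFrame):
        df = source
    else:
        if isinstance(source, Path) or "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        df = pd.read_csv(io.StringIO(text), sep=sep, engine="python")

    shorthand_col = cmap.get("variant")
    explicit = all(cmap.get(k) in df.columns for k in ("residue", "ref", "alt"))
    if shorthand_col not in df.columns and not explicit:
        raise SchemaError(
            f"cannot resolve variant columns: need {shorthand_col!r} or "
            f"residue/ref/alt via column_map; table has {list(df.columns)}"
        )

    class_col = cmap.get("class")
    source_col = cmap.get("source")
    records: list[VariantRecord] = []
    rejects: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        raw = str(row.get(shorthand_col, "")) if shorthand_col in df.columns else ""
        try:
            if shorthand_col in df.columns and str(row[shorthand_col]).strip():
                num, ref, alt = parse_protein_change(row[shorthand_col])
            elif explicit:
                num = int(row[cmap["residue"]])
                ref = _normalize_aa(str(row[cmap["ref"]]))
                alt = _normalize_aa(str(row[cmap["alt"]]))
                if ref is None or alt is None:
                    raise ValidationError("unknown amino-acid code")
                raw = f"{ref}{num}{alt}"
            else:
                raise ValidationError("empty variant field")
            vclass = "nonsense" if alt == "*" else "missense"
            if class_col in df.columns and pd.notna(row[class_col]):
                declared = str(row[class_col]).strip().lower()
                if declared and declared not in ("missense", "nonsense"):
                    vclass = "other"
                elif declared:
                    vclass = declared
            label = str(row[source_col]) if source_col in df.columns else ""
            records.append(
                VariantRecord(num + residue_offset, ref, alt, vclass, label)
            )
        except (ValidationError, ValueError, TypeError) as exc:
            rejects.append((int(idx), raw, str(exc)))

    if filter_classes is not None:
        keep = set(filter_classes)
        kept = [r for r in records if r.variant_class in keep]
        rejects.extend(
            (-1, f"{r.ref_aa}{r.residue_number}{r.alt_aa}", f"filtered class {r.variant_class}")
            for r in records
            if r.variant_class not in keep
        )
        records = kept
    warning = None
    if not records:
        warning = "no variant records remain after validation/filtering"
    return ParseResult(records=records, rejects=rejects, warning=warning)


def substitution_diversity(records: Sequence[VariantRecord]) -> dict[int, set[str]]:
    """Per-residue set of distinct alternate amino acids (duplicates collapse)."""
    out: dict[int, set[str]] = {}
    for rec in records:
        out.setdefault(rec.residue_number, set()).add(rec.alt_aa)
    return out


@dataclass
class HotspotTable:
    """Per-residue distinct-substitution counts with hotspot flags."""

    threshold: int
    alts: dict[int, set[str]]
    n_records: int = 0

    @property
    def affected_residues(self) -> list[int]:
        return sorted(self.alts)

    @property
    def hotspot_residues(self) -> list[int]:
        return sorted(r for r, a in self.alts.items() if len(a) >= self.threshold)

    def n_distinct(self, residue: int) -> int:
        return len(self.alts.get(residue, ()))

    def is_hotspot(self, residue: int) -> bool:
        return self.n_distinct(residue) >= self.threshold

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": r,
                "n_distinct": len(a),
                "alts": ",".join(sorted(a)),
                "is_hotspot": len(a) >= self.threshold,
            }
            for r, a in sorted(self.alts.items())
        ]
        return pd.DataFrame(rows, columns=["residue", "n_distinct", "alts", "is_hotspot"])

    def summary(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_affected_residues": len(self.alts),
            "n_hotspots": len(self.hotspot_residues),
            "threshold": self.threshold,
        }


def call_hotspots(
    diversity: Mapping[int, set[str]] | Sequence[VariantRecord],
    threshold: int = 2,
    n_records: int | None = None,
) -> HotspotTable:
    """Flag residues whose distinct-alternate count reaches ``threshold``
    (default 2 — 'mutated to two or more types of amino acids')."""
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    if not isinstance(diversity, Mapping):
        records = list(diversity)
        if n_records is None:
            n_records = len(records)
        diversity = substitution_diversity(records)
    return HotspotTable(
        threshold=threshold,
        alts={int(k): set(v) for k, v in diversity.items()},
        n_records=n_records or 0,
    )
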