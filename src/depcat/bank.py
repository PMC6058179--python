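"""Calibrated item banks: data model, validation, I/O, packaged fixtures.

An :class:`ItemBank` is an ordered collection of :class:`ItemParameters`
(one of five polytomous IRT parameterizations) with optional per-item
content metadata (:class:`ItemMetadata`).  Two fixture banks ship with the
package:

``cat_depression_68.csv``
    The calibrated 68-item depression bank (graded response model, four
    response categories).  Item 43's printed parameters were not
    recoverable from the source table; its discrimination is reconstructed
    from the bank's printed mean (a = 2.29) and its thresholds are the
    midpoint of the neighbouring rows — the row is flagged
    ``(reconstructed)`` in its content field.

``item_ledger_117.csv``
    The 117-item development ledger: symptom domain, one-factor loadings
    from the two confirmatory runs, and the psychometric reason(s) each
    excluded item was dropped (CFA, Q3, S-X2, Discrimination, DIF).
"""

from __future__ import annotations

import io
import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODELS = ("GRM", "GPCM", "PCM", "RSM", "NRM")
SYMPTOM_DOMAINS = ("behavior", "cognition", "mood", "somatic", "suicide")

__all__ = [
    "ItemParameters",
    "ItemMetadata",
    "ItemBank",
    "load_bank",
    "save_bank",
    "validate_bank",
    "summarize_bank",
    "load_cat_depression_bank",
    "load_item_ledger",
]


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of one polytomous item under a given IRT model.

    Exactly the block required by ``model`` must be present:

    - GRM: ``a`` > 0 and strictly increasing thresholds ``b`` (length K-1).
    - GPCM: ``a`` > 0 and step parameters ``steps`` (length K-1).
    - PCM: common slope ``a`` and ``steps``.
    - RSM: common slope ``a``, item ``location``, shared category offsets
      ``taus`` (length K-1).
    - NRM: category ``slopes`` and ``intercepts`` (length K), identified by
      fixing the first-category slope and intercept to zero.
    """

    item_id: str
    model: str
    n_categories: int
    a: float | None = None
    b: tuple[float, ...] | None = None
    steps: tuple[float, ...] | None = None
    location: float | None = None
    taus: tuple[float, ...] | None = None
    slopes: tuple[float, ...] | None = None
    intercepts: tuple[float, ...] | None = None

    def __post_init__(self):
        for name in ("b", "steps", "taus", "slopes", "intercepts"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, tuple(float(v) for v in val))

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        v: list[str] = []
        K = self.n_categories
        if self.model not in MODELS:
            return [f"{self.item_id}: unknown model {self.model!r}"]
        if K < 2:
            v.append(f"{self.item_id}: n_categories must be >= 2, got {K}")
            return v

        def need(names: Iterable[str]):
            names = set(names)
            for nm in ("a", "b", "steps", "location", "taus", "slopes",
                       "intercepts"):
                present = getattr(self, nm) is not None
                if nm in names and not present:
                    v.append(f"{self.item_id}: {self.model} requires {nm!r}")
                if nm not in names and present:
                    v.append(f"{self.item_id}: {self.model} does not use"
                             f" {nm!r}")

        if self.model == "GRM":
            need(["a", "b"])
            if self.a is not None and self.a <= 0:
                v.append(f"{self.item_id}: nonpositive discrimination"
                         f" a={self.a}")
            if self.b is not None:
                if len(self.b) != K - 1:
                    v.append(f"{self.item_id}: expected {K - 1} thresholds,"
                             f" got {len(self.b)}")
                elif any(x >= y for x, y in zip(self.b, self.b[1:])):
                    v.append(f"{self.item_id}: thresholds not increasing"
                             f" {self.b}")
        elif self.model in ("GPCM", "PCM"):
            need(["a", "steps"])
            if self.model == "GPCM" and self.a is not None and self.a <= 0:
                v.append(f"{self.item_id}: nonpositive discrimination"
                         f" a={self.a}")
            if self.steps is not None and len(self.steps) != K - 1:
                v.append(f"{self.item_id}: expected {K - 1} steps,"
                         f" got {len(self.steps)}")
        elif self.model == "RSM":
            need(["a", "location", "taus"])
            if self.taus is not None and len(self.taus) != K - 1:
                v.append(f"{self.item_id}: expected {K - 1} taus,"
                         f" got {len(self.taus)}")
        elif self.model == "NRM":
            need(["slopes", "intercepts"])
            for nm in ("slopes", "intercepts"):
                val = getattr(self, nm)
                if val is None:
                    continue
                if len(val) != K:
                    v.append(f"{self.item_id}: expected {K} {nm},"
                             f" got {len(val)}")
                elif val[0] != 0.0:
                    v.append(f"{self.item_id}: NRM first-category {nm[:-1]}"
                             f" must be fixed at 0 for identification")
        return v


@dataclass(frozen=True)
class ItemMetadata:
    """Content bookkeeping for one item of a development ledger."""

    item_id: str
    symptom_domain: str | None = None
    source_scale: str | None = None
    abbreviated_content: str | None = None
    #: ordered atomic exclusion reasons, e.g. ("Q3", "S-X2"); empty = retained
    exclusion_reasons: tuple[str, ...] = ()

    def violations(self) -> list[str]:
        if (self.symptom_domain is not None
                and self.symptom_domain not in SYMPTOM_DOMAINS):
            return [f"{self.item_id}: unknown symptom_domain"
                    f" {self.symptom_domain!r}"]
        return []


@dataclass
class ItemBank:
    """Ordered collection of calibrated items with parallel metadata.

    Responses are coded 0..K-1 internally; ``category_offset`` records the
    coding of source data files (1 if responses on disk are 1..K).
    """

    items: list[ItemParameters]
    metadata: list[ItemMetadata] = field(default_factory=list)
    name: str = "bank"
    category_offset: int = 0

    def __post_init__(self):
        if not self.metadata:
            self.metadata = [ItemMetadata(item_id=it.item_id)
                             for it in self.items]
        if len(self.metadata) != len(self.items):
            raise ValueError("metadata length does not match items")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, idx: int) -> ItemParameters:
        return self.items[idx]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_categories(self) -> int:
        return self.items[0].n_categories if self.items else 0

    def index_of(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    def subset(self, item_ids: Sequence[str], name: str | None = None
               ) -> "ItemBank":
        keep = set(item_ids)
        items = [it for it in self.items if it.item_id in keep]
        meta = [m for m in self.metadata if m.item_id in keep]
        return ItemBank(items, meta, name=name or self.name,
                        category_offset=self.category_offset)

    def discriminations(self) -> np.ndarray:
        return np.array([it.a for it in self.items], dtype=float)


def validate_bank(bank: ItemBank) -> list[str]:
    """Collect every invariant violation in the bank (empty list = valid)."""
    report: list[str] = []
    seen = Counter(bank.item_ids)
    for item_id, n in seen.items():
        if n > 1:
            report.append(f"{item_id}: duplicate item_id ({n} occurrences)")
    ks = {it.n_categories for it in bank.items}
    if len(ks) > 1:
        report.append(f"bank {bank.name!r}: mixed n_categories {sorted(ks)}")
    for it in bank.items:
        report.extend(it.violations())
    for m in bank.metadata:
        report.extend(m.violations())
    return report


def summarize_bank(bank: ItemBank) -> dict:
    """Bank-level summary: size, discrimination range, symptom counts."""
    if len(bank) == 0:
        raise ValueError("cannot summarize an empty bank")
    a = np.array([it.a for it in bank.items if it.a is not None], dtype=float)
    domains = Counter(m.symptom_domain for m in bank.metadata
                      if m.symptom_domain is not None)
    out = {
        "n_items": len(bank),
        "mean_a": float(a.mean()) if a.size else None,
        "min_a": float(a.min()) if a.size else None,
        "max_a": float(a.max()) if a.size else None,
        "by_symptom_domain": dict(domains),
    }
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _bank_to_frame(bank: ItemBank) -> pd.DataFrame:
    K = max((it.n_categories for it in bank.items), default=2)
    rows = []
    for it, m in zip(bank.items, bank.metadata):
        row: dict = {"item_id": it.item_id, "model": it.model,
                     "n_categories": it.n_categories}
        if it.a is not None:
            row["a"] = it.a
        for nm, width in (("b", K - 1), ("steps", K - 1), ("taus", K - 1),
                          ("slopes", K), ("intercepts", K)):
            vals = getattr(it, nm)
            if vals is not None:
                prefix = {"b": "b", "steps": "d", "taus": "tau",
                          "slopes": "ak", "intercepts": "ck"}[nm]
                for i, vv in enumerate(vals, start=1):
                    row[f"{prefix}{i}"] = vv
        if it.location is not None:
            row["location"] = it.location
        if m.symptom_domain is not None:
            row["symptom_domain"] = m.symptom_domain
        if m.abbreviated_content is not None:
            row["content"] = m.abbreviated_content
        if m.source_scale is not None:
            row["source_scale"] = m.source_scale
        rows.append(row)
    return pd.DataFrame(rows)


def _collect(row: pd.Series, prefix: str) -> tuple[float, ...] | None:
    vals = []
    i = 1
    while f"{prefix}{i}" in row.index:
        v = row[f"{prefix}{i}"]
        if pd.isna(v):
            break
        vals.append(float(v))
        i += 1
    return tuple(vals) if vals else None


def _frame_to_bank(df: pd.DataFrame, name: str, source: str) -> ItemBank:
    required = {"item_id", "model", "n_categories"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing required column(s)"
                         f" {sorted(missing)}")
    items, meta = [], []
    for idx, row in df.iterrows():
        model = str(row["model"]).upper()
        kwargs: dict = {}
        if "a" in df.columns and not pd.isna(row.get("a")):
            kwargs["a"] = float(row["a"])
        thresholds = _collect(row, "b")
        if model == "GRM":
            kwargs["b"] = thresholds
        elif model in ("GPCM", "PCM"):
            kwargs["steps"] = _collect(row, "d")
        elif model == "RSM":
            if "location" in df.columns and not pd.isna(row.get("location")):
                kwargs["location"] = float(row["location"])
            kwargs["taus"] = _collect(row, "tau")
        elif model == "NRM":
            kwargs["slopes"] = _collect(row, "ak")
            kwargs["intercepts"] = _collect(row, "ck")
        try:
            item = ItemParameters(item_id=str(row["item_id"]), model=model,
                                  n_categories=int(row["n_categories"]),
                                  **kwargs)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{source}: malformed row {idx}"
                             f" (item_id={row['item_id']!r}): {exc}") from exc
        items.append(item)
        meta.append(ItemMetadata(
            item_id=str(row["item_id"]),
            symptom_domain=(str(row["symptom_domain"])
                            if "symptom_domain" in df.columns
                            and not pd.isna(row.get("symptom_domain"))
                            else None),
            abbreviated_content=(str(row["content"])
                                 if "content" in df.columns
                                 and not pd.isna(row.get("content"))
                                 else None),
            source_scale=(str(row["source_scale"])
                          if "source_scale" in df.columns
                          and not pd.isna(row.get("source_scale"))
                          else None),
        ))
    bank = ItemBank(items, meta, name=name)
    problems = validate_bank(bank)
    if problems:
        raise ValueError(f"{source}: invalid bank:\n  " + "\n  ".join(problems))
    return bank


def load_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Load a validated item bank from a CSV or JSON file.

    Raises ``ValueError`` naming the offending column/row for malformed
    input; an invariant violation anywhere aborts the load (no partial
    bank is returned).
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty bank file")
    name = path.stem
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["items"])
        name = payload.get("name", name)
    else:
        raise ValueError(f"unknown bank format {fmt!r}")
    if df.empty:
        raise ValueError(f"{path}: bank file contains no items")
    return _frame_to_bank(df, name=name, source=str(path))


def save_bank(bank: ItemBank, path: str | Path,
              format: str | None = None) -> None:
    """Write a bank to CSV or JSON.

    The writer emits a canonical form: saving, loading, and saving again
    produces bit-identical files for the same format.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    df = _bank_to_frame(bank)
    if fmt == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
        path.write_text(buf.getvalue())
    elif fmt == "json":
        records = json.loads(df.to_json(orient="records", double_precision=15))
        path.write_text(json.dumps({"name": bank.name, "items": records},
                                   indent=1) + "\n")
    else:
        raise ValueError(f"unknown bank format {fmt!r}")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("depcat.data").joinpath(name)


def load_cat_depression_bank() -> ItemBank:
    """The calibrated 68-item GRM depression bank (four categories)."""
    with resources.as_file(_data_path("cat_depression_68.csv")) as p:
        return load_bank(p, format="csv")


def load_item_ledger() -> pd.DataFrame:
    """The 117-item development ledger.

    Columns: ``item_id``, ``symptom_domain``, ``loading_cfa1``,
    ``loading_cfa2`` (blank for items dropped at the first factor run),
    and ``exclusion_reasons`` ('+'-joined ordered atomic reasons; blank for
    the 68 retained items).
    """
    with resources.as_file(_data_path("item_ledger_117.csv")) as p:
        df = pd.read_csv(p, dtype={"item_id": str})
    df["exclusion_reasons"] = df["exclusion_reasons"].fillna("")
    df["reason_list"] = df["exclusion_reasons"].map(
        lambda s: tuple(s.split("+")) if s else ())
    return df
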