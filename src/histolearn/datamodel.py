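"""Dataset representation: directory scanning, count summaries, splitting.

The on-disk layout mirrors the BreakHis breast-cancer histopathology
collection: images grouped by optical magnification tier (40X/100X/200X/400X)
and tumor class (benign/malignant), optionally with a histological-subtype
subdirectory. A :class:`Manifest` is the flat in-memory index of such a tree;
all downstream stages (training pools, evaluation strata) are annotations on
its records, so train/test and labeled/unlabeled membership is always
auditable from one CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("histolearn")

__all__ = [
    "MAGNIFICATIONS",
    "CLASSES",
    "SUBTYPES",
    "BREAKHIS_PUBLISHED_COUNTS",
    "ImageRecord",
    "Manifest",
    "CountSummary",
    "scan_dataset",
    "summarize",
    "split_dataset",
    "sample_initial_labeled",
    "breakhis_reference_summary",
]

MAGNIFICATIONS = (40, 100, 200, 400)
CLASSES = ("benign", "malignant")

SUBTYPES: dict[str, tuple[str, ...]] = {
    "benign": ("adenosis", "fibroadenoma", "phyllodes_tumor", "tubular_adenoma"),
    "malignant": ("ductal_carcinoma", "lobular_carcinoma",
                  "mucinous_carcinoma", "papillary_carcinoma"),
}

#: Published per-(subtype, magnification) sample counts of the BreakHis
#: collection, as reported in its accompanying literature. Kept as a
#: reference fixture for accounting checks; note the published per-class
#: narrative total for benign (2,480) differs from the sum of these cells
#: (2,320) — the cells are reported as-is.
BREAKHIS_PUBLISHED_COUNTS: dict[tuple[str, str], dict[int, int]] = {
    ("benign", "adenosis"): {40: 114, 100: 113, 200: 111, 400: 106},
    ("benign", "fibroadenoma"): {40: 193, 100: 260, 200: 264, 400: 137},
    ("benign", "phyllodes_tumor"): {40: 149, 100: 150, 200: 140, 400: 130},
    ("benign", "tubular_adenoma"): {40: 109, 100: 121, 200: 108, 400: 115},
    ("malignant", "ductal_carcinoma"): {40: 864, 100: 903, 200: 896, 400: 788},
    ("malignant", "lobular_carcinoma"): {40: 156, 100: 170, 200: 163, 400: 137},
    ("malignant", "mucinous_carcinoma"): {40: 205, 100: 222, 200: 196, 400: 169},
    ("malignant", "papillary_carcinoma"): {40: 145, 100: 142, 200: 135, 400: 138},
}

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}

#: Directory dialects: ordered path levels under the root. The subtype level
#: is optional in either dialect — a single extra directory between the class
#: level and the file is read as the subtype.
LAYOUTS: dict[str, tuple[str, ...]] = {
    "mag-class": ("magnification", "class"),
    "class-mag": ("class", "magnification"),
}


@dataclass
class ImageRecord:
    """One histology image and its annotations."""

    id: str
    path: str
    magnification: int
    class_label: str
    subtype: str = "unknown"
    split: str = ""          # "", "train", "test"
    pool: str = "none"       # "labeled", "unlabeled", "none"

    def __post_init__(self):
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"magnification {self.magnification} not in "
                             f"{MAGNIFICATIONS}")
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label {self.class_label!r} not in {CLASSES}")
        if self.subtype != "unknown" and \
                self.subtype not in SUBTYPES[self.class_label]:
            raise ValueError(f"subtype {self.subtype!r} inconsistent with "
                             f"class {self.class_label!r}")


@dataclass
class Manifest:
    """Ordered collection of image records with unique ids."""

    records: list[ImageRecord] = field(default_factory=list)
    source_root: str = ""
    seed: int = 0
    n_skipped: int = 0

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def select(self, split: str | None = None, pool: str | None = None,
               magnification: int | None = None) -> list[ImageRecord]:
        out = self.records
        if split is not None:
            out = [r for r in out if r.split == split]
        if pool is not None:
            out = [r for r in out if r.pool == pool]
        if magnification is not None:
            out = [r for r in out if r.magnification == magnification]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [r.id for r in self.records],
            "path": [r.path for r in self.records],
            "magnification": [r.magnification for r in self.records],
            "class": [r.class_label for r in self.records],
            "subtype": [r.subtype for r in self.records],
            "split": [r.split for r in self.records],
            "pool": [r.pool for r in self.records],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source_root: str = "",
                   seed: int = 0) -> "Manifest":
        df = df.fillna({"split": "", "pool": "none", "subtype": "unknown"})
        records = [ImageRecord(
            id=str(row["id"]), path=str(row["path"]),
            magnification=int(row["magnification"]),
            class_label=str(row["class"]),
            subtype=str(row["subtype"]) or "unknown",
            split=str(row["split"]),
            pool=str(row["pool"]) or "none",
        ) for row in df.to_dict("records")]
        return cls(records=records, source_root=source_root, seed=seed)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Manifest":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


@dataclass
class CountSummary:
    """Counts per (magnification, class, subtype) with per-class totals."""

    table: pd.DataFrame          # columns: magnification, class, subtype, count
    totals: dict[str, int]

    @classmethod
    def from_cells(cls, cells: dict[tuple[str, str], dict[int, int]],
                   ) -> "CountSummary":
        rows = [(mag, cl, st, n)
                for (cl, st), per_mag in cells.items()
                for mag, n in per_mag.items()]
        table = pd.DataFrame(rows, columns=["magnification", "class",
                                            "subtype", "count"])
        if (table["count"] < 0).any():
            raise ValueError("negative count cell")
        totals = table.groupby("class")["count"].sum().to_dict()
        return cls(table=table.sort_values(
            ["class", "subtype", "magnification"]).reset_index(drop=True),
            totals={c: int(n) for c, n in totals.items()})

    def count(self, magnification: int | None = None, class_label: str | None = None,
              subtype: str | None = None) -> int:
        t = self.table
        if magnification is not None:
            t = t[t["magnification"] == magnification]
        if class_label is not None:
            t = t[t["class"] == class_label]
        if subtype is not None:
            t = t[t["subtype"] == subtype]
        return int(t["count"].sum())


def breakhis_reference_summary() -> CountSummary:
    """Count summary built from the published BreakHis sample distribution."""
    return CountSummary.from_cells(BREAKHIS_PUBLISHED_COUNTS)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _parse_magnification(token: str) -> int | None:
    token = token.strip().lower().rstrip("x")
    try:
        mag = int(token)
    except ValueError:
        return None
    return mag if mag in MAGNIFICATIONS else None


def _parse_class(token: str) -> str | None:
    token = token.strip().lower()
    return token if token in CLASSES else None


def scan_dataset(root: str | Path, layout: str = "mag-class") -> Manifest:
    """Index a magnification/class directory tree into a Manifest.

    Files are ordered lexicographically by path; unparseable subdirectories
    and non-image files are skipped with a logged warning and counted in
    ``Manifest.n_skipped``. An extra directory level between the class level
    and the image file is read as the histological subtype.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {list(LAYOUTS)}")
    levels = LAYOUTS[layout]

    records: list[ImageRecord] = []
    n_skipped = 0
    for fpath in sorted(root.rglob("*")):
        if not fpath.is_file():
            continue
        if fpath.suffix.lower() not in IMAGE_EXTENSIONS:
            logger.warning("skipping non-image file %s", fpath)
            n_skipped += 1
            continue
        rel = fpath.relative_to(root).parts
        if len(rel) < len(levels) + 1:
            logger.warning("skipping %s: path too shallow for layout %s",
                           fpath, layout)
            n_skipped += 1
            continue
        parsed: dict[str, object] = {}
        ok = True
        for level_name, token in zip(levels, rel):
            value = (_parse_magnification(token) if level_name == "magnification"
                     else _parse_class(token))
            if value is None:
                logger.warning("skipping %s: cannot parse %r as %s",
                               fpath, token, level_name)
                ok = False
                break
            parsed[level_name] = value
        if not ok:
            n_skipped += 1
            continue
        middle = rel[len(levels):-1]
        subtype = middle[0].lower() if len(middle) == 1 else "unknown"
        cls = str(parsed["class"])
        if subtype != "unknown" and subtype not in SUBTYPES[cls]:
            subtype = "unknown"
        records.append(ImageRecord(
            id=str(Path(*rel)), path=str(fpath),
            magnification=int(parsed["magnification"]),  # type: ignore[arg-type]
            class_label=cls, subtype=subtype))
    return Manifest(records=records, source_root=str(root), n_skipped=n_skipped)


def summarize(manifest: Manifest) -> CountSummary:
    """Counts per (magnification, class, subtype) plus per-class totals."""
    cells: dict[tuple[str, str], dict[int, int]] = {}
    for r in manifest.records:
        per_mag = cells.setdefault((r.class_label, r.subtype), {})
        per_mag[r.magnification] = per_mag.get(r.magnification, 0) + 1
    if not cells:
        empty = pd.DataFrame(columns=["magnification", "class", "subtype", "count"])
        return CountSummary(table=empty, totals={c: 0 for c in CLASSES})
    return CountSummary.from_cells(cells)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(manifest: Manifest, test_fraction: float,
                  seed: int) -> Manifest:
    """Stratified train/test split by (magnification, class).

    Within each stratum, round_half_up(test_fraction * n) records are
    assigned to the test split, chosen uniformly at random but
    deterministically for a given seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    new_records = [replace(r) for r in manifest.records]
    strata: dict[tuple[int, str], list[int]] = {}
    for i, r in enumerate(new_records):
        strata.setdefault((r.magnification, r.class_label), []).append(i)
    for key in sorted(strata):
        idx = strata[key]
        if len(idx) < 2:
            logger.warning("stratum %s has %d record(s); split by rounding only",
                           key, len(idx))
        n_test = _round_half_up(test_fraction * len(idx))
        order = rng.permutation(len(idx))
        test_set = {idx[j] for j in order[:n_test]}
        for i in idx:
            new_records[i].split = "test" if i in test_set else "train"
            new_records[i].pool = "none"
    return Manifest(records=new_records, source_root=manifest.source_root,
                    seed=seed, n_skipped=manifest.n_skipped)


def sample_initial_labeled(manifest: Manifest, labeled_fraction: float,
                           seed: int) -> Manifest:
    """Mark a random labeled subset of the training split.

    round_half_up(labeled_fraction * |train|) train records become the
    initial labeled pool; the remaining train records are the unlabeled
    pool; test records keep pool "none".
    """
    if not 0 < labeled_fraction <= 1:
        raise ValueError("labeled_fraction must be in (0, 1]")
    new_records = [replace(r) for r in manifest.records]
    train_idx = [i for i, r in enumerate(new_records) if r.split == "train"]
    if not train_idx:
        raise ValueError("manifest has no training split; run split_dataset first")
    n_labeled = _round_half_up(labeled_fraction * len(train_idx))
    if n_labeled == 0:
        raise ValueError(
            f"labeled_fraction {labeled_fraction} yields an empty labeled pool "
            f"for {len(train_idx)} training records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_idx))
    labeled = {train_idx[j] for j in order[:n_labeled]}
    for i, r in enumerate(new_records):
        if r.split == "train":
            r.pool = "labeled" if i in labeled else "unlabeled"
        else:
            r.pool = "none"
    return Manifest(records=new_records, source_root=manifest.source_root,
                    seed=seed, n_skipped=manifest.n_skipped)
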