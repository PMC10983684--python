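"""Dataset manifests: per-image records with label, split and provenance.

A manifest is the single source of truth for dataset accounting.  Each
record carries ``path`` (relative to the image root), ``label``, ``split``
(``train``/``test``), ``provenance`` (``original``/``augmented``) and, for
augmented copies, the ``source_path`` of the original they derive from.
The published study's bookkeeping (879 originals -> 586 train + 293 test,
augmented to a 1280-image training set) is plain arithmetic on such a
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DatasetManifest", "split_dataset"]

COLUMNS = ["path", "label", "split", "provenance", "source_path"]
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class DatasetManifest:
    records: pd.DataFrame
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.records = df[COLUMNS].reset_index(drop=True)
        if not self.class_names:
            self.class_names = sorted(df["label"].unique())
        self.validate()

    # -- construction ---------------------------------------------------------
    @classmethod
    def from_directory(cls, root: str | Path, split: str = "train") -> "DatasetManifest":
        """Ingest a directory-per-class tree ``root/<class>/<file>``."""
        root = Path(root)
        rows = []
        for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for f in sorted(class_dir.iterdir()):
                if f.suffix.lower() in IMAGE_SUFFIXES:
                    rows.append((f"{class_dir.name}/{f.name}", class_dir.name,
                                 split, "original", ""))
        if not rows:
            raise ValueError(f"no images found under {root}")
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    @classmethod
    def from_counts(cls, per_class_counts: dict[str, int],
                    split: str = "train") -> "DatasetManifest":
        """Synthesize a manifest of placeholder originals from class counts
        (for accounting that needs no pixels)."""
        rows = [(f"{c}/{c}_{i:04d}.png", c, split, "original", "")
                for c, n in per_class_counts.items() for i in range(n)]
        return cls(pd.DataFrame(rows, columns=COLUMNS),
                   class_names=list(per_class_counts))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        df = self.records
        bad = set(df["label"]) - set(self.class_names)
        if bad:
            raise ValueError(f"labels outside class_names: {sorted(bad)}")
        if not df["split"].isin(["train", "test"]).all():
            raise ValueError("split must be 'train' or 'test'")
        if not df["provenance"].isin(["original", "augmented"]).all():
            raise ValueError("provenance must be 'original' or 'augmented'")
        aug = df[df["provenance"] == "augmented"]
        originals = set(df.loc[df["provenance"] == "original", "path"])
        orphans = set(aug["source_path"]) - originals
        if orphans:
            raise ValueError(f"augmented records reference unknown originals: "
                             f"{sorted(orphans)[:3]}...")

    # -- accounting -----------------------------------------------------------
    def per_class_counts(self, split: str | None = None,
                         provenance: str | None = None) -> pd.Series:
        df = self.records
        if split is not None:
            df = df[df["split"] == split]
        if provenance is not None:
            df = df[df["provenance"] == provenance]
        counts = df["label"].value_counts()
        return counts.reindex(self.class_names, fill_value=0)

    def accounting_table(self) -> pd.DataFrame:
        """Per-class originals / original-train / final-train / test counts,
        with a grand-total row."""
        table = pd.DataFrame({
            "originals": self.per_class_counts(provenance="original"),
            "train_originals": self.per_class_counts("train", "original"),
            "train_final": self.per_class_counts("train"),
            "test": self.per_class_counts("test"),
        })
        table.loc["Total"] = table.sum()
        return table.astype(int)

    def subset(self, split: str) -> "DatasetManifest":
        df = self.records[self.records["split"] == split]
        if df.empty:
            raise ValueError(f"no records in split '{split}'")
        return DatasetManifest(df.copy(), class_names=list(self.class_names))

    def __len__(self) -> int:
        return len(self.records)


def split_dataset(manifest: DatasetManifest,
                  test_fraction: float | None = None,
                  seed: int = 0,
                  test_counts: dict[str, int] | None = None) -> DatasetManifest:
    """Stratified train/test split of a manifest of originals.

    Either ``test_fraction`` (per class, ``round(fraction * n_c)`` images go
    to the test split, half-up) or an explicit ``test_counts`` map — the
    latter reproduces printed per-class splits exactly.  Selection within a
    class is a seeded shuffle, so splits are reproducible.
    """
    df = manifest.records
    if (df["provenance"] != "original").any():
        raise ValueError("split_dataset expects a manifest of originals only")
    if (test_fraction is None) == (test_counts is None):
        raise ValueError("give exactly one of test_fraction or test_counts")
    rng = np.random.default_rng(seed)
    split_col = pd.Series("train", index=df.index)
    for cls in manifest.class_names:
        idx = df.index[df["label"] == cls].to_numpy()
        if len(idx) == 0:
            raise ValueError(f"class '{cls}' has no images")
        if test_counts is not None:
            n_test = int(test_counts.get(cls, 0))
        else:
            n_test = int(np.floor(test_fraction * len(idx) + 0.5))
        if n_test > len(idx):
            raise ValueError(f"test count {n_test} exceeds class size "
                             f"{len(idx)} for '{cls}'")
        chosen = rng.permutation(idx)[:n_test]
        split_col.loc[chosen] = "test"
    out = df.copy()
    out["split"] = split_col
    return DatasetManifest(out, class_names=list(manifest.class_names))
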