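"""Individual-level dataset partitioning, leakage auditing, and training-set balancing.

Frames of the same animal are strongly correlated (shared anatomy, different
speckle), so splits are drawn over *individuals*, never frames: a fixed
number of individuals per sex goes to validation and test, the remainder to
training, and every frame inherits its animal's split. `check_leakage`
audits any frame-level membership for individuals straddling splits — the
failure mode that inflates image-level random splits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_seed, rng_for

SPLITS = ("train", "val", "test")

IndividualKey = tuple[str, str, str, str]  # (individual_id, location, sex, size_class)
KEY_COLUMNS = ["individual_id", "location", "sex", "size_class"]


def individual_keys(manifest: pd.DataFrame) -> pd.Series:
    """Composite individual key per manifest row."""
    return pd.Series(
        list(zip(*(manifest[c] for c in KEY_COLUMNS))), index=manifest.index, name="individual_key"
    )


@dataclass
class SplitAssignment:
    """Mapping individual key -> split, plus the seed that produced it."""

    assignment: dict[IndividualKey, str]
    seed: int

    def __post_init__(self):
        bad = {s for s in self.assignment.values()} - set(SPLITS)
        if bad:
            raise ValueError(f"unknown splits {bad}")

    def individuals(self, split: str) -> list[IndividualKey]:
        return sorted(k for k, s in self.assignment.items() if s == split)

    def frame_split(self, manifest: pd.DataFrame) -> pd.Series:
        """Per-frame split membership derived from the individual assignment."""
        keys = individual_keys(manifest)
        unknown = sorted(set(keys) - set(self.assignment))
        if unknown:
            raise KeyError(f"manifest contains individuals absent from the assignment: {unknown[:5]}")
        return keys.map(self.assignment).rename("split")

    def frames(self, manifest: pd.DataFrame, split: str) -> pd.DataFrame:
        return manifest.loc[self.frame_split(manifest) == split].copy()

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(zip(KEY_COLUMNS, k), split=s, seed=self.seed) for k, s in sorted(self.assignment.items())]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SplitAssignment":
        df = pd.read_csv(path)
        assignment = {tuple(r[c] for c in KEY_COLUMNS): r["split"] for _, r in df.iterrows()}
        return cls(assignment, int(df["seed"].iloc[0]) if len(df) else 0)


def assign_splits(
    roster: pd.DataFrame,
    n_val_per_sex: int = 4,
    n_test_per_sex: int = 4,
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign individuals to splits, stratified by sex.

    ``roster`` is a manifest or any frame with the individual key columns;
    duplicate rows per individual are fine. Within each sex,
    ``n_val_per_sex`` individuals are drawn without replacement to
    validation and ``n_test_per_sex`` to test; the remainder train.
    """
    keys = sorted(set(individual_keys(roster)))
    by_sex: dict[str, list[IndividualKey]] = {}
    for k in keys:
        by_sex.setdefault(k[2], []).append(k)
    assignment: dict[IndividualKey, str] = {}
    for sex in sorted(by_sex):
        members = by_sex[sex]
        need = n_val_per_sex + n_test_per_sex
        if len(members) < need + 1:
            raise ValueError(
                f"sex {sex!r} has {len(members)} individuals; need at least {need + 1} "
                f"for {n_val_per_sex} val + {n_test_per_sex} test + 1 train"
            )
        order = rng_for(seed, "split", sex).permutation(len(members))
        for rank, idx in enumerate(order):
            if rank < n_val_per_sex:
                split = "val"
            elif rank < need:
                split = "test"
            else:
                split = "train"
            assignment[members[idx]] = split
    return SplitAssignment(assignment, seed)


@dataclass
class LeakageReport:
    """Outcome of a leakage audit over a frame-level split membership."""

    leaked_individuals: list[IndividualKey]
    per_split: dict[str, dict[str, int]]  # split -> {"frames": n, "individuals": n}

    @property
    def n_leaked(self) -> int:
        return len(self.leaked_individuals)

    @property
    def is_clean(self) -> bool:
        return self.n_leaked == 0


def check_leakage(
    assignment: "SplitAssignment | pd.Series | dict",
    manifest: pd.DataFrame,
) -> LeakageReport:
    """Audit a split for individuals present in more than one partition.

    ``assignment`` may be a :class:`SplitAssignment` (leak-free by
    construction, still audited), or a frame-level membership: a dict/Series
    mapping manifest ``path`` -> split (e.g. an image-level random split).
    """
    keys = individual_keys(manifest)
    if isinstance(assignment, SplitAssignment):
        frame_split = assignment.frame_split(manifest)
    else:
        mapping = assignment if isinstance(assignment, dict) else dict(assignment)
        missing = [p for p in manifest["path"] if p not in mapping]
        if missing:
            raise KeyError(f"frames missing from assignment: {missing[:5]}")
        frame_split = manifest["path"].map(mapping).rename("split")
    df = pd.DataFrame({"key": keys, "split": frame_split})
    splits_per_ind = df.groupby("key")["split"].nunique()
    leaked = sorted(splits_per_ind.index[splits_per_ind > 1])
    per_split = {
        s: {
            "frames": int((df["split"] == s).sum()),
            "individuals": int(df.loc[df["split"] == s, "key"].nunique()),
        }
        for s in sorted(df["split"].unique())
    }
    return LeakageReport(leaked, per_split)


def balance_training_set(
    train_manifest: pd.DataFrame,
    augmenter,
    target: int | str = "auto",
    cap: int | None = None,
    seed: int = 0,
    loader=None,
    writer=None,
) -> pd.DataFrame:
    """Top up under-represented training individuals with augmented copies.

    ``target="auto"`` equalizes toward each sex's maximum per-individual
    frame count (capped at ``cap``). Source frames cycle in filename order;
    each augmented copy is produced by ``augmenter(image, seed)`` and written
    through ``writer(path, image)`` with ``loader(path)`` supplying sources
    (omit both for a pure bookkeeping pass). Original rows are never removed;
    appended rows carry ``synthetic=True`` and a ``*_augNN.png`` path.
    """
    if train_manifest.empty:
        raise ValueError("empty training manifest")
    df = train_manifest.copy()
    if "synthetic" not in df.columns:
        df["synthetic"] = False
    keys = individual_keys(df)
    counts = keys.value_counts()
    if target == "auto":
        sex_max = {}
        for k, n in counts.items():
            sex_max[k[2]] = max(sex_max.get(k[2], 0), n)
        target_for = {k: sex_max[k[2]] for k in counts.index}
    else:
        t = int(target)
        if t < int(counts.max()):
            raise ValueError("explicit target must be >= the largest per-individual count")
        target_for = {k: t for k in counts.index}
    new_rows = []
    for key in sorted(counts.index):
        goal = min(target_for[key], cap) if cap is not None else target_for[key]
        have = int(counts[key])
        originals = df.loc[(keys == key) & (~df["synthetic"])].sort_values("path")
        for j in range(max(0, goal - have)):
            src = originals.iloc[j % len(originals)]
            stem, ext = os.path.splitext(src["path"])
            row = src.to_dict()
            row["path"] = f"{stem}_aug{j:02d}{ext}"
            row["synthetic"] = True
            if loader is not None and writer is not None:
                img = augmenter(loader(src["path"]), seed=child_seed(seed, "balance", *key, j))
                writer(row["path"], img)
            new_rows.append(row)
    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return df
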