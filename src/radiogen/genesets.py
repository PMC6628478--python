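"""Gene set collections (GMT format) with optional pathway categories."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GeneSetCollection:
    """Map of set id -> member gene ids, plus an optional category label map."""

    sets: dict[str, list[str]]
    categories: dict[str, str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if len(members) != len(set(members)):
                raise ValueError(f"duplicate members in gene set {sid!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: list[str], min_set_size: int = 5
                 ) -> tuple["GeneSetCollection", list[str]]:
        """Intersect every set with ``universe``; drop sets below
        ``min_set_size``.  Returns (restricted collection, dropped set ids)."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        dropped: list[str] = []
        for sid, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if len(inter) >= min_set_size:
                kept[sid] = inter
            else:
                dropped.append(sid)
        cats = None
        if self.categories is not None:
            cats = {s: self.categories[s] for s in kept if s in self.categories}
        return GeneSetCollection(sets=kept, categories=cats,
                                 descriptions=self.descriptions), dropped


def read_gmt(path: str | Path, categories_path: str | Path | None = None
             ) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: set id, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line!r}")
        sid, desc, members = parts[0], parts[1], parts[2:]
        if sid in sets:
            raise ValueError(f"duplicate gene set id {sid!r}")
        sets[sid] = [m for m in members if m]
        descriptions[sid] = desc
    categories = None
    if categories_path is not None:
        categories = read_category_map(categories_path)
    return GeneSetCollection(sets=sets, categories=categories,
                             descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for sid, members in collection.sets.items():
        desc = collection.descriptions.get(sid, "na")
        lines.append("\t".join([sid, desc] + list(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(Path(path), sep="\t")
    if df.shape[1] < 2:
        raise ValueError("category map needs two columns: set id, category")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_category_map(categories: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"set_id": list(categories), "category": list(categories.values())}
    ).to_csv(Path(path), sep="\t", index=False)


def generate_geneset_collection(
    n_sets: int,
    size_range: tuple[int, int],
    universe: list[str],
    category_labels: list[str],
    rng_seed: int,
) -> GeneSetCollection:
    """Random gene sets sampled from ``universe``.

    Members are drawn without replacement within a set and independently
    across sets; each set is assigned a category label cyclically so every
    label is represented.  Deterministic given the seed.
    """
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError(
            f"max set size {hi} exceeds universe size {len(universe)}"
        )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([rng_seed])))
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    width = len(str(n_sets))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = [universe[j] for j in
                   rng.choice(len(universe), size=size, replace=False)]
        sid = f"SET{i + 1:0{width}d}"
        sets[sid] = members
        categories[sid] = category_labels[i % len(category_labels)]
    return GeneSetCollection(sets=sets, categories=categories)
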