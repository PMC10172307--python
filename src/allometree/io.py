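"""Reading, validating and reconciling the three pipeline inputs.

The pipeline consumes (a) a specimen-level measurement table (CSV), (b) a
species metadata table (CSV) and (c) a time-calibrated phylogeny (Newick).
This module owns the canonical trait ordering, the validation invariants
(strictly positive measurements, unique specimen ids, consistent
order/partition assignments) and the sample-size pruning rule applied before
species-level trajectory fitting.

Trait count is parameterised by the CSV header: any set of >= 2 measurement
columns is accepted, held in a fixed alphabetical order so that coefficient
vectors are comparable across every downstream module. ``DEFAULT_TRAITS``
lists the 14 cranial linear measurements used by default throughout the
synthetic generator (breadth of braincase, palatal/condylobasal/nasal/dentary
lengths, muzzle and mandibular-body heights, tooth-row lengths, orbit,
occipital plate, zygomatic breadth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Phylo

__all__ = [
    "DEFAULT_TRAITS", "PARTITIONS", "ORDERS", "ORDER_TO_PARTITION", "DIETS",
    "SpecimenTable", "SpeciesMeta", "ValidationError",
    "load_dataset", "prune_by_sample_size", "write_dataset",
]

# Canonical default trait labels, alphabetical (case-insensitive).
DEFAULT_TRAITS: tuple[str, ...] = (
    "BB", "BPAL", "CBL", "HD", "HM", "LC", "LD",
    "LN", "LPAL", "LPos", "OH", "ORB", "UPos", "ZB",
)

PARTITIONS = ("Ameridelphia", "Australidelphia")

ORDER_TO_PARTITION: dict[str, str] = {
    "Didelphimorphia": "Ameridelphia",
    "Paucituberculata": "Ameridelphia",
    "Microbiotheria": "Australidelphia",
    "Dasyuromorphia": "Australidelphia",
    "Diprotodontia": "Australidelphia",
    "Notoryctemorphia": "Australidelphia",
    "Peramelemorphia": "Australidelphia",
}
ORDERS = tuple(sorted(ORDER_TO_PARTITION))

DIETS = ("animalivory", "herbivory", "mycophagy", "omnivory")


class ValidationError(ValueError):
    pass


def _norm_species(name: str) -> str:
    """Exact matching after whitespace/underscore normalisation."""
    return "_".join(str(name).strip().split()).replace("__", "_")


@dataclass
class SpecimenTable:
    """Specimen-level measurement table.

    ``df`` has columns ``specimen_id``, ``species`` and one column per trait
    (mm, strictly positive). ``traits`` fixes the column order used by every
    downstream vector.
    """

    df: pd.DataFrame
    traits: tuple[str, ...] = DEFAULT_TRAITS
    dropped_species: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.validate()

    def validate(self) -> None:
        need = {"specimen_id", "species", *self.traits}
        missing = need - set(self.df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        if self.df["specimen_id"].duplicated().any():
            dups = self.df.loc[self.df["specimen_id"].duplicated(), "specimen_id"]
            raise ValidationError(f"duplicate specimen ids: {list(dups[:5])}")
        m = self.df[list(self.traits)].to_numpy(dtype=float)
        bad = ~np.isfinite(m) | (m <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "non-positive or non-finite measurement: specimen "
                f"{self.df['specimen_id'].iloc[i]!r}, trait {self.traits[j]!r}, "
                f"value {m[i, j]!r}"
            )

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    @property
    def n_specimens(self) -> int:
        return len(self.df)

    def counts(self) -> pd.Series:
        return self.df["species"].value_counts()

    def measurements(self) -> np.ndarray:
        """(n_specimens, p) array in canonical trait order."""
        return self.df[list(self.traits)].to_numpy(dtype=float)

    def subset(self, species: list[str]) -> "SpecimenTable":
        keep = self.df["species"].isin(species)
        return SpecimenTable(self.df.loc[keep].reset_index(drop=True), self.traits)


@dataclass
class SpeciesMeta:
    """Per-species metadata: partition, order, diet, optional body mass (g)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        need = {"species", "partition", "order", "diet"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.df["species"].duplicated().any():
            raise ValidationError("duplicate species in metadata")
        bad_diet = set(self.df["diet"]) - set(DIETS)
        if bad_diet:
            raise ValidationError(f"unknown diet states: {sorted(bad_diet)}")
        bad_part = set(self.df["partition"]) - set(PARTITIONS)
        if bad_part:
            raise ValidationError(f"unknown partitions: {sorted(bad_part)}")
        for _, row in self.df.iterrows():
            expect = ORDER_TO_PARTITION.get(row["order"])
            if expect is None:
                raise ValidationError(f"unknown order: {row['order']!r}")
            if expect != row["partition"]:
                raise ValidationError(
                    f"order {row['order']!r} is inconsistent with partition "
                    f"{row['partition']!r} for species {row['species']!r}"
                )
        if "body_mass" in self.df.columns:
            bm = pd.to_numeric(self.df["body_mass"], errors="coerce")
            if (bm.dropna() <= 0).any():
                raise ValidationError("non-positive body mass")

    def lookup(self, column: str) -> dict[str, str]:
        return dict(zip(self.df["species"], self.df[column]))


def load_dataset(
    specimen_csv: str,
    meta_csv: str,
    tree_newick: str,
    traits: tuple[str, ...] | None = None,
) -> tuple[SpecimenTable, SpeciesMeta, Phylo]:
    """Load and reconcile the three inputs.

    Species names are matched exactly after whitespace/underscore
    normalisation. Species present in the specimen table but absent from the
    tree are reported with a warning and retained: tree-based stages subset
    to the intersection later.
    """
    spec_df = pd.read_csv(specimen_csv)
    if traits is None:
        reserved = {"specimen_id", "species"}
        traits = tuple(sorted((c for c in spec_df.columns if c not in reserved),
                              key=str.casefold))
    spec_df["species"] = spec_df["species"].map(_norm_species)
    table = SpecimenTable(spec_df, traits)

    meta_df = pd.read_csv(meta_csv)
    meta_df["species"] = meta_df["species"].map(_norm_species)
    meta = SpeciesMeta(meta_df)

    tree = Phylo.from_newick(tree_newick)
    tree.labels = [_norm_species(x) for x in tree.labels]

    not_in_tree = sorted(set(table.species) - set(tree.labels))
    if not_in_tree:
        import warnings
        warnings.warn(
            f"{len(not_in_tree)} species absent from tree (retained in table; "
            f"tree-based stages subset): {not_in_tree[:5]}", stacklevel=2)
    not_in_meta = sorted(set(table.species) - set(meta.df["species"]))
    if not_in_meta:
        raise ValidationError(f"species missing from metadata: {not_in_meta[:5]}")
    return table, meta, tree


def prune_by_sample_size(table: SpecimenTable, min_n: int = 15) -> SpecimenTable:
    """Retain species with at least ``min_n`` specimens.

    The default of 15 keeps only species whose ontogenetic series exceeds the
    number of shape variables, the condition required for stable
    species-level trajectory estimation.
    """
    if min_n < 2:
        raise ValueError("min_n must be >= 2")
    counts = table.counts()
    keep = sorted(counts.index[counts >= min_n])
    dropped = tuple(sorted(counts.index[counts < min_n]))
    if not keep:
        raise ValidationError("pruning removed every species")
    out = table.subset(keep)
    out.dropped_species = dropped
    return out


def write_dataset(table: SpecimenTable, meta: SpeciesMeta, tree: Phylo,
                  specimen_csv: str, meta_csv: str, tree_newick: str) -> None:
    cols = ["specimen_id", "species", *table.traits]
    table.df[cols].to_csv(specimen_csv, index=False)
    meta.df.to_csv(meta_csv, index=False)
    with open(tree_newick, "w") as fh:
        fh.write(tree.to_newick() + "\n")
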