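"""Biome availability windows and tip biome-occupancy matrices.

The occupancy matrix is the central object of the single- versus
multiple-biome comparison: each row is a taxon, each column a biome, and a
cell is 1 when the species consistently occurs (and matures) in that biome.
``mode="multiple"`` allows any non-empty row; ``mode="single"`` requires
exactly one biome per taxon and is produced from a multiple-biome matrix by
collapsing each row to its modal biome (the biome forming the largest
proportion of the species' range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomeAvailability",
    "OccupancyMatrix",
    "read_occupancy",
    "write_occupancy",
    "collapse_to_modal",
    "NZ_BIOMES",
]


@dataclass(frozen=True)
class BiomeAvailability:
    """Ordered biomes with the age (Ma) at which each became available.

    ``appearance_times[biome]`` is the age before present at which the biome
    first existed; a biome absent from the mapping has always been available.
    Biome order is fixed by ``biomes`` and is used for every tie-break in the
    package (lowest index wins).
    """

    biomes: tuple[str, ...]
    appearance_times: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.biomes)) != len(self.biomes):
            raise ValueError("duplicate biome names")
        unknown = set(self.appearance_times) - set(self.biomes)
        if unknown:
            raise ValueError(f"appearance times for unknown biomes: {sorted(unknown)}")
        if any(t < 0 for t in self.appearance_times.values()):
            raise ValueError("appearance times must be >= 0 Ma")
        if not any(b not in self.appearance_times for b in self.biomes):
            raise ValueError("at least one biome must always be available")

    @property
    def n_biomes(self) -> int:
        return len(self.biomes)

    def appearance(self, biome: str) -> float:
        """Appearance age; ``inf`` when the biome has always existed."""
        return self.appearance_times.get(biome, np.inf)

    def boundaries(self) -> list[float]:
        """Distinct finite appearance ages, ascending (stratum limits)."""
        return sorted({float(t) for t in self.appearance_times.values()})

    def stratum_of(self, age: float) -> int:
        """Index of the stratum containing ``age``; 0 is the youngest.

        Stratum ``s`` covers ages in ``(b[s-1], b[s]]`` so a node sitting
        exactly on a biome's appearance age may still occupy that biome.
        """
        return int(np.searchsorted(self.boundaries(), age, side="left"))

    def n_strata(self) -> int:
        return len(self.boundaries()) + 1

    def available_in_stratum(self, stratum: int) -> np.ndarray:
        """Boolean availability per biome throughout the given stratum."""
        bounds = self.boundaries() + [np.inf]
        hi = bounds[stratum]
        return np.array([self.appearance(b) >= hi for b in self.biomes])

    def available_at(self, age: float) -> np.ndarray:
        return np.array([self.appearance(b) >= age for b in self.biomes])


#: The three-biome New Zealand system: Forest always present, Open habitats
#: below treeline since 4 Ma, Alpine since 1.9 Ma.
NZ_BIOMES = BiomeAvailability(
    biomes=("Forest", "Open", "Alpine"),
    appearance_times={"Open": 4.0, "Alpine": 1.9},
)


class OccupancyError(ValueError):
    pass


@dataclass
class OccupancyMatrix:
    """Binary taxa × biomes presence matrix."""

    taxa: list[str]
    biomes: tuple[str, ...]
    presence: np.ndarray  # (n_taxa, n_biomes) of 0/1
    mode: str = "multiple"  # "single" | "multiple"

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=int)
        if self.presence.shape != (len(self.taxa), len(self.biomes)):
            raise OccupancyError("presence shape does not match taxa × biomes")
        if not np.isin(self.presence, (0, 1)).all():
            raise OccupancyError("presence entries must be 0 or 1")
        if len(set(self.taxa)) != len(self.taxa):
            raise OccupancyError("duplicate taxon names")
        rowsums = self.presence.sum(axis=1)
        if (rowsums == 0).any():
            bad = self.taxa[int(np.where(rowsums == 0)[0][0])]
            raise OccupancyError(f"taxon {bad!r} occupies no biome (all-zero row)")
        if self.mode not in ("single", "multiple"):
            raise OccupancyError(f"unknown mode {self.mode!r}")
        if self.mode == "single" and (rowsums != 1).any():
            bad = self.taxa[int(np.where(rowsums != 1)[0][0])]
            raise OccupancyError(
                f"mode='single' but taxon {bad!r} occupies {rowsums.max()} biomes"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> np.ndarray:
        return self.presence[self.taxa.index(taxon)]

    def state_masks(self) -> np.ndarray:
        """Per-taxon occupancy encoded as a bitmask over biome indices."""
        bits = 1 << np.arange(len(self.biomes))
        return (self.presence * bits).sum(axis=1)

    def specialists(self) -> int:
        """Number of taxa occupying exactly one biome."""
        return int((self.presence.sum(axis=1) == 1).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.taxa, columns=list(self.biomes))

    def check_against_tree(self, tree) -> None:
        if set(self.taxa) != set(tree.tip_labels):
            missing = set(tree.tip_labels) - set(self.taxa)
            extra = set(self.taxa) - set(tree.tip_labels)
            raise OccupancyError(
                f"taxa do not match tree tips (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )

    def reordered(self, taxa: list[str]) -> "OccupancyMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return OccupancyMatrix(list(taxa), self.biomes, self.presence[idx], self.mode)


def read_occupancy(path, dialect: str = "csv", biomes: tuple[str, ...] | None = None,
                   mode: str = "multiple") -> OccupancyMatrix:
    """Read an occupancy matrix.

    ``dialect="csv"``: header row ``taxon,<biome>,...`` and 0/1 cells.
    ``dialect="geography"``: the LAGRANGE/PHYLIP-style format used by
    biogeography tools — a header line ``n_taxa n_biomes`` followed by one
    line per taxon, ``name 0/1-string``; biome names are not stored in the
    file and must be supplied (or default to ``B0, B1, ...``).
    """
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise OccupancyError(f"{path}: non-binary cell in occupancy CSV")
        return OccupancyMatrix(
            [str(t) for t in df.index], tuple(df.columns), vals, mode
        )
    if dialect == "geography":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        head = lines[0].split()
        if len(head) < 2:
            raise OccupancyError(f"{path}: geography header must be 'n_taxa n_biomes'")
        n_taxa, n_biomes = int(head[0]), int(head[1])
        body = lines[1:]
        if len(body) != n_taxa:
            raise OccupancyError(
                f"{path}: header declares {n_taxa} taxa but file has {len(body)}"
            )
        taxa, rows = [], []
        for ln in body:
            name, bits = ln.split(None, 1)
            bits = bits.strip()
            if len(bits) != n_biomes or set(bits) - {"0", "1"}:
                raise OccupancyError(
                    f"{path}: taxon {name!r} has range string {bits!r}, "
                    f"expected {n_biomes} binary digits"
                )
            taxa.append(name)
            rows.append([int(c) for c in bits])
        if biomes is None:
            biomes = tuple(f"B{i}" for i in range(n_biomes))
        if len(biomes) != n_biomes:
            raise OccupancyError(
                f"{path}: {len(biomes)} biome names given for {n_biomes} columns"
            )
        return OccupancyMatrix(taxa, tuple(biomes), np.array(rows), mode)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_occupancy(occ: OccupancyMatrix, path, dialect: str = "csv") -> None:
    if dialect == "csv":
        df = occ.to_frame()
        df.index.name = "taxon"
        df.to_csv(path)
    elif dialect == "geography":
        with open(path, "w") as fh:
            fh.write(f"{occ.n_taxa} {len(occ.biomes)}\n")
            for t, row in zip(occ.taxa, occ.presence):
                fh.write(f"{t} {''.join(str(int(x)) for x in row)}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def collapse_to_modal(occ: OccupancyMatrix, weights: np.ndarray | pd.DataFrame) -> OccupancyMatrix:
    """Collapse a multiple-biome matrix to single (modal-biome) coding.

    ``weights`` gives, per taxon, the proportion of the species' range in
    each biome; each row must be positive only on occupied biomes and sum to
    1.  Each taxon keeps only its argmax-weight biome; exact ties go to the
    lowest biome index.
    """
    if isinstance(weights, pd.DataFrame):
        weights = weights.loc[occ.taxa, list(occ.biomes)].to_numpy()
    w = np.asarray(weights, dtype=float)
    if w.shape != occ.presence.shape:
        raise OccupancyError("weights shape does not match occupancy matrix")
    if np.any((w > 0) & (occ.presence == 0)):
        t = occ.taxa[int(np.where(((w > 0) & (occ.presence == 0)).any(axis=1))[0][0])]
        raise OccupancyError(f"taxon {t!r} has weight on an unoccupied biome")
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-6):
        raise OccupancyError("weights must sum to 1 per taxon")
    modal = np.argmax(w, axis=1)  # argmax takes the first (lowest index) on ties
    pres = np.zeros_like(occ.presence)
    pres[np.arange(occ.n_taxa), modal] = 1
    return OccupancyMatrix(list(occ.taxa), occ.biomes, pres, mode="single")
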