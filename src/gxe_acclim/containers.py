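"""Core data containers: study design, expression and probe matrices.

The experimental layout is a balanced nested factorial: two geographic
origins (N = Northern, heat-sensitive; S = Southern, heat-tolerant), two
clones nested within each origin, two acclimation temperatures (18 and
28 degrees C) and an equal number of biological replicates per
clone x temperature cell (three in the default design, 24 samples total).
Every statistical routine in this package assumes this balance and
refuses unbalanced input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORIGINS = ("N", "S")
TEMPERATURES = (18, 28)

DESIGN_COLUMNS = ["sample_id", "clone_id", "origin", "temperature", "replicate"]


class DesignError(ValueError):
    """Raised when a sample design table violates the balanced nested layout."""


class MatrixError(ValueError):
    """Raised when an expression/probe matrix is malformed."""


class AlignmentError(ValueError):
    """Raised when matrix sample ids and design sample ids disagree."""


@dataclass(frozen=True)
class StudyDesign:
    """Balanced sample-to-factor mapping.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``clone_id``,
        ``origin`` ('N'/'S'), ``temperature`` (18/28) and ``replicate``.
        Stored in canonical order (origin, clone, temperature, replicate).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        t = t[DESIGN_COLUMNS].copy()
        t["temperature"] = t["temperature"].astype(int)
        t["replicate"] = t["replicate"].astype(int)
        t["sample_id"] = t["sample_id"].astype(str)
        t["clone_id"] = t["clone_id"].astype(str)
        t["origin"] = t["origin"].astype(str)

        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample ids: {dups}")
        bad_origin = set(t["origin"]) - set(ORIGINS)
        if bad_origin:
            raise DesignError(f"origin must be one of {ORIGINS}, got {sorted(bad_origin)}")
        bad_temp = set(t["temperature"]) - set(TEMPERATURES)
        if bad_temp:
            raise DesignError(f"temperature must be one of {TEMPERATURES}, got {sorted(bad_temp)}")
        if set(t["origin"]) != set(ORIGINS):
            raise DesignError("both origins N and S must be present")

        # each clone belongs to exactly one origin
        per_clone = t.groupby("clone_id")["origin"].nunique()
        if (per_clone != 1).any():
            raise DesignError("each clone must belong to exactly one origin")
        clones_per_origin = t.groupby("origin")["clone_id"].nunique()
        if clones_per_origin.nunique() != 1:
            raise DesignError(
                f"unbalanced design: unequal clone counts per origin {dict(clones_per_origin)}"
            )
        # every clone x temperature cell has the same replicate count >= 2
        cells = t.groupby(["clone_id", "temperature"]).size()
        expected_cells = t["clone_id"].nunique() * 2
        if len(cells) != expected_cells or cells.nunique() != 1:
            raise DesignError(
                "unbalanced design: every clone must appear at both temperatures "
                f"with equal replicate counts (got cells {dict(cells)})"
            )
        if int(cells.iloc[0]) < 2:
            raise DesignError("at least 2 replicates per clone x temperature cell required")

        t = t.sort_values(["origin", "clone_id", "temperature", "replicate"], kind="mergesort")
        t = t.reset_index(drop=True)
        object.__setattr__(self, "table", t)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def n_replicates(self) -> int:
        return int(self.table.groupby(["clone_id", "temperature"]).size().iloc[0])

    @property
    def clones(self) -> list[str]:
        return sorted(self.table["clone_id"].unique())

    @property
    def n_clones_per_origin(self) -> int:
        return int(self.table.groupby("origin")["clone_id"].nunique().iloc[0])

    def clone_origin(self) -> dict[str, str]:
        return dict(self.table.drop_duplicates("clone_id")[["clone_id", "origin"]].values)

    def x_temperature(self) -> np.ndarray:
        """Effect coding of temperature: -1 for 18 C, +1 for 28 C."""
        return np.where(self.table["temperature"].to_numpy() == 28, 1.0, -1.0)

    def x_origin(self) -> np.ndarray:
        """Effect coding of origin: -1 for N, +1 for S."""
        return np.where(self.table["origin"].to_numpy() == "S", 1.0, -1.0)

    def subset_origin(self, origin: str) -> "StudyDesign":
        if origin not in ORIGINS:
            raise DesignError(f"unknown origin {origin!r}")
        return RegionDesign(self.table[self.table["origin"] == origin].reset_index(drop=True))

    def swap_origins(self) -> "StudyDesign":
        """Return a design with N and S labels exchanged (clone ids kept)."""
        t = self.table.copy()
        t["origin"] = t["origin"].map({"N": "S", "S": "N"})
        return StudyDesign(t)

    @classmethod
    def default(cls, n_replicates: int = 3) -> "StudyDesign":
        """The study layout: 2 origins x 2 clones x 2 temperatures x replicates."""
        rows = []
        for origin, clones in (("N", ("N1", "N2")), ("S", ("S1", "S2"))):
            for clone in clones:
                for temp in TEMPERATURES:
                    for rep in range(1, n_replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"{clone}_T{temp}_r{rep}",
                                "clone_id": clone,
                                "origin": origin,
                                "temperature": temp,
                                "replicate": rep,
                            }
                        )
        return cls(pd.DataFrame(rows))

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "clone_id": str}))


class RegionDesign(StudyDesign):
    """A single-origin slice of a :class:`StudyDesign` (2 clones x 2 T x reps).

    Relaxes the two-origin requirement but keeps the clone/temperature balance
    checks; used by the region-wise ANOVA.
    """

    def __post_init__(self) -> None:  # noqa: D105
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        t = t[DESIGN_COLUMNS].copy()
        t["temperature"] = t["temperature"].astype(int)
        if t["origin"].nunique() != 1:
            raise DesignError("region design must contain exactly one origin")
        cells = t.groupby(["clone_id", "temperature"]).size()
        if len(cells) != t["clone_id"].nunique() * 2 or cells.nunique() != 1:
            raise DesignError("unbalanced region design")
        t = t.sort_values(["clone_id", "temperature", "replicate"], kind="mergesort")
        object.__setattr__(self, "table", t.reset_index(drop=True))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise MatrixError("duplicate gene ids in expression matrix")
        if v.columns.duplicated().any():
            raise MatrixError("duplicate sample ids in expression matrix")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MatrixError("non-numeric cells in expression matrix")
        object.__setattr__(self, "values", v.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def align_to(self, design: StudyDesign) -> "ExpressionMatrix":
        """Reorder columns to the design's canonical sample order."""
        if set(self.sample_ids) != set(design.sample_ids):
            only_m = sorted(set(self.sample_ids) - set(design.sample_ids))
            only_d = sorted(set(design.sample_ids) - set(self.sample_ids))
            raise AlignmentError(
                f"sample id mismatch; matrix-only={only_m}, design-only={only_d}"
            )
        return ExpressionMatrix(self.values[design.sample_ids])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


@dataclass(frozen=True)
class ProbeMatrix:
    """Probes x samples matrix with a probe-to-gene map (1-3 probes per gene)."""

    values: pd.DataFrame = field(repr=False)
    probe_to_gene: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise MatrixError("duplicate probe ids")
        mapped = self.probe_to_gene.reindex(self.values.index)
        if mapped.isna().any():
            missing = mapped[mapped.isna()].index.tolist()[:5]
            raise MatrixError(f"probes without a gene mapping, e.g. {missing}")
        counts = mapped.value_counts()
        if (counts > 3).any():
            raise MatrixError("more than 3 probes map to a single gene")
        object.__setattr__(self, "values", self.values.astype(float))
        object.__setattr__(self, "probe_to_gene", mapped.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def to_tsv(self, matrix_path, map_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id", float_format="%.10g")
        self.probe_to_gene.rename("gene_id").to_csv(
            map_path, sep="\t", index_label="probe_id"
        )

    @classmethod
    def from_tsv(cls, matrix_path, map_path) -> "ProbeMatrix":
        vals = pd.read_csv(matrix_path, sep="\t", index_col=0)
        vals.index = vals.index.astype(str)
        pmap = pd.read_csv(map_path, sep="\t", index_col=0)["gene_id"].astype(str)
        pmap.index = pmap.index.astype(str)
        return cls(vals, pmap)
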