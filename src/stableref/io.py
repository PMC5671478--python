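"""Readers, writers and validated containers for expression, design, Cq and
annotation data.

All downstream analysis consumes only the types defined here:

* :class:`ExpressionMatrix` — transcripts × samples grid of FPKM or counts.
* :class:`SampleDesign` — sample → condition-group (and replicate) mapping.
* :class:`CqMatrix` — genes × samples RT-qPCR quantification cycles with
  per-gene amplification efficiencies and calibration-curve metadata.
* :class:`IsoformIndex` — transcript → gene mapping with per-gene isoform
  counts derived from a GTF annotation.

Tabular files are plain TSV/CSV; the Cufflinks ``*.fpkm_tracking`` layout is
accepted as an expression-matrix dialect.  All writers prepend a one-line
``#stableref <version> <command>`` comment header, and all readers skip
``#`` comment lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("stableref")

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "CqMatrix",
    "IsoformIndex",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_design",
    "write_sample_design",
    "read_cq_table",
    "write_cq_table",
    "read_efficiency_table",
    "build_isoform_index",
    "load_panel_qc",
    "load_panel_ranks",
    "MISSING_CQ_MARKERS",
]

#: cell values treated as a missing Cq ("not detected")
MISSING_CQ_MARKERS = {"", "ND", "NA", "NaN", "nan", "N/A", "-", "Undetermined"}


def _header(command: str = "") -> str:
    from stableref import __version__

    return f"#stableref {__version__} {command}".rstrip()


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts × samples table of non-negative expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by transcript id, columns by sample id. FPKM or counts.
    unit_label : str
        ``"FPKM"`` or ``"count"`` — informational only.
    """

    values: pd.DataFrame
    unit_label: str = "FPKM"

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
            self.values = v
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"non-numeric or missing expression value at transcript "
                f"{v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value {arr[r, c]} at transcript "
                f"{v.index[r]!r}, sample {v.columns[c]!r}"
            )
        self.values = v.astype(float)

    @property
    def transcript_ids(self) -> list[str]:
        return [str(t) for t in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleDesign:
    """Mapping of samples to condition groups and replicate numbers."""

    group_of: dict[str, str]
    replicate_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_of:
            raise ValueError("design must contain at least one sample")
        if not self.replicate_of:
            counter: dict[str, int] = {}
            for s, g in self.group_of.items():
                counter[g] = counter.get(g, 0) + 1
                self.replicate_of[s] = counter[g]
        for s, r in self.replicate_of.items():
            if r < 1:
                raise ValueError(f"replicate number of sample {s!r} must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_of)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]


@dataclass
class CqMatrix:
    """Genes × samples grid of RT-qPCR quantification cycles.

    ``NaN`` cells mark missing / not-detected reactions.  ``efficiency_of``
    holds the per-cycle amplification factor of each assay (2.0 = perfect
    doubling) and defaults to 2.0 for genes absent from the mapping.
    """

    cq: pd.DataFrame
    efficiency_of: dict[str, float] = field(default_factory=dict)
    r2_of: dict[str, float] | None = None

    def __post_init__(self) -> None:
        cq = self.cq
        if not isinstance(cq, pd.DataFrame):
            cq = pd.DataFrame(cq)
            self.cq = cq
        if cq.index.has_duplicates:
            raise ValueError("duplicate gene ids in Cq table")
        if cq.columns.has_duplicates:
            raise ValueError("duplicate sample ids in Cq table")
        arr = cq.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("infinite Cq value")
        self.cq = cq.astype(float)
        for g, e in self.efficiency_of.items():
            if not 1.0 < e <= 2.2:
                raise ValueError(
                    f"amplification efficiency of {g!r} is {e}; must be in (1, 2.2]"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.cq.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.cq.columns]

    def efficiency(self, gene: str) -> float:
        return float(self.efficiency_of.get(gene, 2.0))

    def complete_genes(self) -> list[str]:
        """Gene ids with no missing Cq cell."""
        ok = ~self.cq.isna().any(axis=1)
        return [str(g) for g in self.cq.index[ok]]

    def drop_incomplete(self) -> "CqMatrix":
        """Return a copy restricted to genes with complete Cq rows."""
        keep = self.complete_genes()
        dropped = [g for g in self.gene_ids if g not in set(keep)]
        for g in dropped:
            logger.warning("gene %s excluded: missing Cq cell(s)", g)
        return CqMatrix(
            self.cq.loc[keep].copy(),
            {g: e for g, e in self.efficiency_of.items() if g in set(keep)},
            None if self.r2_of is None else {g: r for g, r in self.r2_of.items() if g in set(keep)},
        )


@dataclass
class IsoformIndex:
    """Transcript → gene mapping with per-gene isoform counts."""

    gene_of: dict[str, str]
    isoform_count_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for g in self.gene_of.values():
            counts[g] = counts.get(g, 0) + 1
        if not self.isoform_count_of:
            self.isoform_count_of = counts
        elif self.isoform_count_of != counts:
            raise ValueError("isoform_count_of inconsistent with gene_of")

    def count_for_transcript(self, transcript_id: str) -> int | None:
        g = self.gene_of.get(transcript_id)
        return None if g is None else self.isoform_count_of[g]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)


def read_expression_matrix(
    path: str | Path, dialect: str = "tsv", unit_label: str = "FPKM"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or a Cufflinks tracking file.

    ``dialect="tsv"`` expects the first column to hold transcript ids and
    every remaining column one sample.  ``dialect="cufflinks_fpkm_tracking"``
    takes the ``tracking_id`` column as transcript id and every column whose
    name ends in ``_FPKM`` as a sample (the suffix is stripped).
    """
    raw = _read_table(path)
    if dialect == "cufflinks_fpkm_tracking":
        if "tracking_id" not in raw.columns:
            raise ValueError("cufflinks dialect requires a 'tracking_id' column")
        fpkm_cols = [c for c in raw.columns if c.endswith("_FPKM")]
        if not fpkm_cols:
            raise ValueError("no '*_FPKM' columns found in tracking file")
        sub = raw[["tracking_id", *fpkm_cols]].copy()
        sub.columns = ["transcript_id"] + [c[: -len("_FPKM")] for c in fpkm_cols]
        raw = sub
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)
    data = raw.drop(columns=[id_col])
    numeric = pd.DataFrame(index=ids.values)
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & data[col].notna()
        if bad.any():
            row = ids[bad].iloc[0]
            raise ValueError(
                f"malformed numeric cell at transcript {row!r}, column {col!r}: "
                f"{data.loc[bad, col].iloc[0]!r}"
            )
        numeric[col] = converted.values
    return ExpressionMatrix(numeric, unit_label=unit_label)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, command: str = "write-matrix"
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(command) + "\n")
        out = matrix.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# sample designs
# ---------------------------------------------------------------------------


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a TSV sample sheet with header ``sample, group, replicate``."""
    raw = _read_table(path)
    required = {"sample", "group"}
    if not required <= set(raw.columns):
        raise ValueError("sample sheet needs 'sample' and 'group' columns")
    group_of = dict(zip(raw["sample"].astype(str), raw["group"].astype(str)))
    if len(group_of) != len(raw):
        raise ValueError("duplicate sample ids in sample sheet")
    replicate_of: dict[str, int] = {}
    if "replicate" in raw.columns:
        replicate_of = {
            str(s): int(r) for s, r in zip(raw["sample"], raw["replicate"])
        }
    return SampleDesign(group_of, replicate_of)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("write-design") + "\n")
        fh.write("sample\tgroup\treplicate\n")
        for s in design.sample_ids:
            fh.write(f"{s}\t{design.group_of[s]}\t{design.replicate_of[s]}\n")


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------


def _parse_cq_cell(x) -> float:
    if pd.isna(x) or str(x).strip() in MISSING_CQ_MARKERS:
        return np.nan
    return float(x)


def read_cq_table(
    path: str | Path,
    layout: str = "wide",
    efficiency_of: dict[str, float] | None = None,
) -> CqMatrix:
    """Read a Cq table.

    ``layout="wide"``: first column gene id, remaining columns one sample
    each.  ``layout="long"``: columns ``gene, sample, replicate, cq``;
    replicate Cq values are averaged arithmetically on the cycle scale into
    one value per gene × sample.  Non-numeric cells (``ND`` etc.) are missing.
    """
    raw = _read_table(path)
    if layout == "wide":
        id_col = raw.columns[0]
        ids = raw[id_col].astype(str)
        grid = raw.drop(columns=[id_col]).map(_parse_cq_cell)
        grid.index = ids.values
    elif layout == "long":
        required = {"gene", "sample", "cq"}
        if not required <= set(raw.columns):
            raise ValueError("long Cq layout needs columns gene, sample, cq")
        raw = raw.assign(cq=raw["cq"].map(_parse_cq_cell))
        grid = (
            raw.pivot_table(index="gene", columns="sample", values="cq",
                            aggfunc="mean", dropna=True)
        )
        # preserve first-appearance order of genes and samples
        gene_order = list(dict.fromkeys(raw["gene"].astype(str)))
        sample_order = list(dict.fromkeys(raw["sample"].astype(str)))
        grid = grid.reindex(index=gene_order, columns=sample_order)
        empty = grid.isna()
        if empty.any().any():
            for g, s in zip(*np.where(empty.to_numpy())):
                logger.warning(
                    "Cq cell gene %s × sample %s has no usable replicate; "
                    "marked missing", gene_order[g], sample_order[s],
                )
    else:
        raise ValueError(f"unknown Cq layout {layout!r}")
    grid.index.name = None
    grid.columns.name = None
    return CqMatrix(grid, efficiency_of=dict(efficiency_of or {}))


def write_cq_table(cq: CqMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("write-cq") + "\n")
        out = cq.cq.copy()
        out.index.name = "gene"
        out.to_csv(fh, sep="\t")


def read_efficiency_table(path: str | Path) -> tuple[dict[str, float], dict[str, float]]:
    """Read per-assay efficiencies (and optional R²) from a TSV.

    Expected columns: ``gene, efficiency`` and optionally ``r2``.
    Returns ``(efficiency_of, r2_of)``; ``r2_of`` is empty when absent.
    """
    raw = _read_table(path)
    if not {"gene", "efficiency"} <= set(raw.columns):
        raise ValueError("efficiency table needs 'gene' and 'efficiency' columns")
    eff = {str(g): float(e) for g, e in zip(raw["gene"], raw["efficiency"])}
    r2 = {}
    if "r2" in raw.columns:
        r2 = {str(g): float(r) for g, r in zip(raw["gene"], raw["r2"])}
    return eff, r2


# ---------------------------------------------------------------------------
# GTF isoform index
# ---------------------------------------------------------------------------


def build_isoform_index(gtf_path: str | Path) -> IsoformIndex:
    """Count distinct transcripts per gene from a GTF annotation.

    Only the ``gene_id`` / ``transcript_id`` attribute pair is used;
    coordinates and strand are irrelevant here.  Features lacking a gene_id
    are skipped with a warning; an annotation yielding no transcripts is an
    error.
    """
    import gffutils

    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(gtf_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    gene_of: dict[str, str] = {}
    for feat in db.all_features():
        tids = feat.attributes.get("transcript_id")
        gids = feat.attributes.get("gene_id")
        if not tids:
            continue
        if not gids:
            logger.warning(
                "feature %s at line with transcript %s lacks gene_id; skipped",
                feat.featuretype, tids[0],
            )
            continue
        gene_of[str(tids[0])] = str(gids[0])
    if not gene_of:
        raise ValueError(f"no transcript/gene attribute pairs found in {gtf_path}")
    return IsoformIndex(gene_of)


# ---------------------------------------------------------------------------
# bundled example panel
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("stableref").joinpath("data", name)))


def load_panel_qc() -> pd.DataFrame:
    """Published efficiency/R² QC values of the bundled 21-assay poplar panel."""
    return pd.read_csv(_data_path("poplar_panel_qc.tsv"), sep="\t", comment="#")


def load_panel_ranks() -> pd.DataFrame:
    """Published per-method stability values/ranks of the bundled 19-gene panel."""
    return pd.read_csv(_data_path("poplar_panel_ranks.tsv"), sep="\t", comment="#")
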