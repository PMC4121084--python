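"""Domain types and file I/O shared by every pipeline stage.

The package works with three tabular inputs, all plain TSV:

* expression matrices (features x samples, any platform),
* TaqMan Ct tables (assays x samples, with an "Undetermined" token for
  cells where no amplification was called),
* two-column ortholog maps (human gene, mouse gene).

Sample columns are tied to developmental stages through a
:class:`StageDesign`; column headers follow the ``<stage>_<replicate>``
convention (e.g. ``4-cell_2``) or an explicit sample->stage mapping.
Positional inference of stages is deliberately refused.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StageDesign",
    "ExpressionMatrix",
    "CtTable",
    "OrthologMap",
    "DataFormatError",
    "get_logger",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ct_table",
    "write_ct_table",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_design",
    "load_yaml",
]

_LOGGER_NAME = "zgaprof"


def get_logger(name: str | None = None) -> logging.Logger:
    """Package logger writing structured lines to stderr."""
    logger = logging.getLogger(_LOGGER_NAME if name is None else f"{_LOGGER_NAME}.{name}")
    root = logging.getLogger(_LOGGER_NAME)
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logger


class DataFormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class StageDesign:
    """Ordered developmental stages and their replicate counts.

    Parameters
    ----------
    stages
        Stage names in developmental order (e.g. MII before 1-cell).
        All stage comparisons in the package use this order, never
        lexical order.
    replicate_count
        Mapping stage -> number of biological replicates.
    species
        Free-text species label, conventionally ``"human"`` or ``"mouse"``.
    """

    stages: tuple[str, ...]
    replicate_count: Mapping[str, int]
    species: str = "human"

    def __init__(self, stages: Sequence[str], replicate_count: Mapping[str, int] | int, species: str = "human"):
        stages = tuple(stages)
        if not stages:
            raise ValueError("design needs at least one stage")
        if len(set(stages)) != len(stages):
            raise ValueError("stage names must be unique")
        if isinstance(replicate_count, int):
            replicate_count = {s: replicate_count for s in stages}
        replicate_count = dict(replicate_count)
        for s in stages:
            n = replicate_count.get(s)
            if n is None or n < 1:
                raise ValueError(f"stage {s!r} needs a positive replicate count")
        object.__setattr__(self, "stages", stages)
        object.__setattr__(self, "replicate_count", replicate_count)
        object.__setattr__(self, "species", species)

    @property
    def n_samples(self) -> int:
        return sum(self.replicate_count[s] for s in self.stages)

    def sample_names(self) -> list[str]:
        """Canonical column names, ``<stage>_<replicate>`` with 1-based replicates."""
        return [f"{s}_{r}" for s in self.stages for r in range(1, self.replicate_count[s] + 1)]

    def sample_stage(self) -> dict[str, str]:
        return {f"{s}_{r}": s for s in self.stages for r in range(1, self.replicate_count[s] + 1)}

    def stage_columns(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise ValueError(f"unknown stage {stage!r}; design stages are {list(self.stages)}")
        return [f"{stage}_{r}" for r in range(1, self.replicate_count[stage] + 1)]

    def consecutive_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "stages": list(self.stages),
            "replicates": dict(self.replicate_count),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StageDesign":
        return cls(d["stages"], d["replicates"], d.get("species", "human"))


@dataclass
class ExpressionMatrix:
    """Features x samples expression values bound to a :class:`StageDesign`.

    ``values`` is a DataFrame whose index holds unique feature identifiers
    and whose columns are exactly the design's sample names, in design
    order. ``scale`` records the measurement scale: ``linear`` (arrays,
    RPKM), ``log2``, ``neg_delta_ct`` or ``ln_rpkm_plus1``.
    """

    values: pd.DataFrame
    design: StageDesign
    scale: str = "linear"
    platform: str = "array"

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise DataFormatError(f"duplicate feature IDs: {dups}")
        expected = self.design.sample_names()
        got = list(self.values.columns)
        if sorted(got) != sorted(expected):
            missing = sorted(set(expected) - set(got))
            extra = sorted(set(got) - set(expected))
            raise DataFormatError(
                f"columns do not match design: missing {missing}, unexpected {extra}"
            )
        if got != expected:
            self.values = self.values[expected]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataFormatError("expression values must be finite (missingness is a CtTable concept)")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.values[self.design.stage_columns(stage)]

    def stage_averages(self) -> pd.DataFrame:
        """Per-(feature, stage) replicate means."""
        return pd.DataFrame(
            {s: self.stage_values(s).mean(axis=1) for s in self.design.stages}
        )


@dataclass
class OrthologMap:
    """Deduplicated (human gene, mouse gene) pairs; 1:many is allowed."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ortholog pairs")

    def mouse_of(self, human_gene: str) -> list[str]:
        return [m for h, m in self.pairs if h == human_gene]

    @property
    def human_genes(self) -> list[str]:
        return [h for h, _ in self.pairs]


@dataclass
class CtTable:
    """Assay x sample qPCR Ct values with detection flags.

    ``ct`` holds cycle numbers (NaN where undetected); ``detected`` is a
    same-shaped boolean frame that is False exactly where the instrument
    called no amplification. ``protocol`` tags the cDNA-synthesis run
    (e.g. ``12ng-random-hexamer``); detection-floor imputation downstream
    operates within one protocol.
    """

    ct: pd.DataFrame
    detected: pd.DataFrame
    design: StageDesign
    protocol: str = "default"

    def __post_init__(self) -> None:
        if self.ct.index.has_duplicates:
            raise DataFormatError("duplicate assay IDs")
        expected = self.design.sample_names()
        if sorted(self.ct.columns) != sorted(expected):
            raise DataFormatError("Ct columns do not match design")
        self.ct = self.ct[expected]
        self.detected = self.detected.reindex(index=self.ct.index, columns=expected)
        det = self.detected.to_numpy(dtype=bool)
        vals = self.ct.to_numpy(dtype=float)
        if not np.isfinite(vals[det]).all():
            raise DataFormatError("detected cells must carry finite Ct values")

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless float64 round-trip


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def read_expression_matrix(
    path: str | Path,
    design: StageDesign,
    scale: str = "linear",
    platform: str = "array",
    sample_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a features x samples TSV into an :class:`ExpressionMatrix`.

    Columns are matched to the design by the ``<stage>_<replicate>``
    header convention, or renamed first through ``sample_map``
    (file column -> canonical sample name). Any column/design mismatch,
    duplicate feature ID or non-numeric cell raises
    :class:`DataFormatError` naming the offender.
    """
    raw = _read_table(path)
    if sample_map:
        raw = raw.rename(columns=dict(sample_map))
    if raw.index.has_duplicates:
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise DataFormatError(f"duplicate feature IDs in {path}: {dups}")
    expected = design.sample_names()
    missing = sorted(set(expected) - set(raw.columns))
    if missing:
        pretty = [f"({m.rsplit('_', 1)[0]}, replicate {m.rsplit('_', 1)[1]})" for m in missing]
        raise DataFormatError(f"{path}: no column for {', '.join(pretty)}")
    numeric = pd.DataFrame(index=raw.index, columns=expected, dtype=float)
    for col in expected:
        try:
            # numpy's parser is correctly rounded (pd.to_numeric is not)
            numeric[col] = raw[col].to_numpy(dtype="U").astype(np.float64)
        except ValueError:
            for row, cell in raw[col].items():
                try:
                    float(cell)
                except ValueError:
                    raise DataFormatError(
                        f"{path}: non-numeric value {cell!r} at row {row!r}, column {col!r}"
                    ) from None
            raise
    return ExpressionMatrix(numeric, design, scale=scale, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="feature_id")


def read_ct_table(
    path: str | Path,
    design: StageDesign,
    undetected_token: str = "Undetermined",
    protocol: str = "default",
    sample_map: Mapping[str, str] | None = None,
) -> CtTable:
    """Read a Ct table whose cells are numeric cycles or the undetected token."""
    raw = _read_table(path)
    if sample_map:
        raw = raw.rename(columns=dict(sample_map))
    expected = design.sample_names()
    missing = sorted(set(expected) - set(raw.columns))
    if missing:
        raise DataFormatError(f"{path}: no column for {missing}")
    ct = pd.DataFrame(np.nan, index=raw.index, columns=expected)
    detected = pd.DataFrame(False, index=raw.index, columns=expected)
    for col in expected:
        for row, cell in raw[col].items():
            text = str(cell).strip()
            if text == undetected_token:
                continue
            try:
                value = float(text)
            except ValueError:
                raise DataFormatError(
                    f"{path}: cell {text!r} at row {row!r}, column {col!r} is neither a Ct "
                    f"value nor the token {undetected_token!r}"
                ) from None
            if value < 0:
                raise DataFormatError(f"{path}: negative Ct {value} at row {row!r}, column {col!r}")
            ct.loc[row, col] = value
            detected.loc[row, col] = True
    return CtTable(ct, detected, design, protocol=protocol)


def write_ct_table(table: CtTable, path: str | Path, undetected_token: str = "Undetermined") -> None:
    out = table.ct.map(lambda v: _FLOAT_FMT % v if np.isfinite(v) else undetected_token)
    out = out.where(table.detected, undetected_token)
    out.to_csv(path, sep="\t", index_label="assay_id")


_HEADER_ALIASES = {
    ("human", "mouse"),
    ("human_gene", "mouse_gene"),
    ("human gene", "mouse gene"),
}


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column (human, mouse) TSV; header row optional.

    Duplicated pairs are dropped (count logged); a row with a field count
    other than two raises :class:`DataFormatError` with its line number.
    """
    log = get_logger("core_io")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected 2"
                )
            pair = (fields[0].strip(), fields[1].strip())
            if lineno == 1 and (pair[0].lower(), pair[1].lower()) in _HEADER_ALIASES:
                continue
            if pair in seen:
                dropped += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if dropped:
        log.info("ortholog map %s: dropped %d duplicate pair(s)", path, dropped)
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("human_gene\tmouse_gene\n")
        for h, m in omap.pairs:
            fh.write(f"{h}\t{m}\n")


def read_design(path: str | Path) -> StageDesign:
    """Read a stage design from a YAML/JSON file (keys: species, stages, replicates)."""
    return StageDesign.from_dict(load_yaml(path))


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataFormatError(f"{path}: expected a mapping at top level")
    return data
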