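"""Core data model for proteomics DEA workflow benchmarking.

Protein-level expression data is held as a protein x sample matrix with a
*matrix type* (how the quantification platform summarised peptides into a
protein value: spectral counts, topN intensity, MaxLFQ, directLFQ, TMT
abundance/ratio/reporter) and a *quantification setting* (platform +
acquisition mode, e.g. FG_DDA = FragPipe on label-free DDA data). The
setting fixes which matrix types, normalization methods, imputation methods
and DEA statistics a workflow may combine; that vocabulary lives in a
declarative, user-editable registry.

Missing values use a single sentinel (NaN) everywhere. For intensity-type
matrices a stored zero means "not quantified" and is converted to missing on
read; for spectral counts zero is a legitimate observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("deabench")

#: Single missing-value sentinel used throughout the package.
MISSING = float("nan")

#: Delimiter marking multi-protein groups in protein identifiers.
PROTEIN_GROUP_DELIMITER = ";"

#: All known expression-matrix types.
MATRIX_TYPES = (
    "counts", "top0", "top1", "top3", "LFQ", "dlfq",
    "abd", "ratio", "phi", "reporter",
)

#: Matrix types whose values are spectral counts (zero is an observation).
COUNT_MATRIX_TYPES = frozenset({"counts"})

#: Quantification settings: platform + acquisition mode.
SETTINGS = ("FG_DDA", "MQ_DDA", "DIANN_DIA", "spt_DIA", "FG_TMT", "MQ_TMT", "generic")

STEPS = ("matrix", "normalization", "imputation", "dea")

_SCALES = ("raw", "log2")


class RegistryError(KeyError):
    """Unknown setting, step or option."""


class MatrixFormatError(ValueError):
    """Malformed expression-matrix file."""


# ---------------------------------------------------------------------------
# Benchmark design constants (the published spike-in panel)
# ---------------------------------------------------------------------------

#: (dataset name, platform, number of contrasts used for benchmarking).
BENCHMARK_DATASETS: tuple[tuple[str, str, int], ...] = (
    ("HYE5600735_LFQ", "DDA", 1),
    ("HYE6600735_LFQ", "DDA", 1),
    ("HYEqe735_LFQ", "DDA", 1),
    ("HYEtims735_LFQ", "DDA", 1),
    ("HYtims134_LFQ", "DDA", 3),
    ("HEtims425_LFQ", "DDA", 3),
    ("YUltq006_LFQ", "DDA", 2),
    ("YUltq099_LFQ", "DDA", 2),
    ("YUltq819_LFQ", "DDA", 3),
    ("HEqe408_LFQ", "DDA", 1),
    ("HYqfl683_LFQ", "DDA", 3),
    ("HYEtims777_LFQ", "DDA", 1),
    ("HYEtims735_DIA", "DIA", 1),
    ("MYtims709_DIA", "DIA", 3),
    ("HEof_n600_DIA", "DIA", 3),
    ("HEof_w600_DIA", "DIA", 3),
    ("HYtims134_DIA", "DIA", 3),
    ("HEqe777_DIA", "DIA", 3),
    ("HEqe408_DIA", "DIA", 1),
    ("HEqe277_TMT10", "TMT", 3),
    ("HYqfl683_TMT11", "TMT", 3),
    ("HYms2faims815_TMT16", "TMT", 3),
    ("HYsps2815_TMT16", "TMT", 3),
    ("HYms2815_TMT16", "TMT", 3),
)

#: Published workflow-grid size per quantification setting.
GRID_SIZES: Mapping[str, int] = {
    "FG_DDA": 7852,
    "MQ_DDA": 7852,
    "DIANN_DIA": 6284,
    "spt_DIA": 6284,
    "FG_TMT": 4720,
    "MQ_TMT": 1584,
}


def platform_contrast_totals() -> dict[str, int]:
    """Total benchmarking contrasts per acquisition platform."""
    totals: dict[str, int] = {}
    for _, platform, n in BENCHMARK_DATASETS:
        totals[platform] = totals.get(platform, 0) + n
    return totals


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Protein x sample expression table.

    ``values`` is a float array with NaN as the missing sentinel. ``scale``
    is ``raw`` (non-negative intensities or counts) or ``log2``.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "raw"
    matrix_type: str = "LFQ"
    setting: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.protein_ids)
        if dupes:
            raise MatrixFormatError(f"duplicate protein IDs: {sorted(dupes)}")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.matrix_type not in MATRIX_TYPES:
            raise ValueError(f"unknown matrix type {self.matrix_type!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.scale == "raw":
            observed = self.values[~np.isnan(self.values)]
            if observed.size and observed.min() < 0:
                raise ValueError("raw-scale matrix contains negative values")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.protein_ids), columns=list(self.sample_ids)
        )

    def copy_with(self, **kwargs) -> "ExpressionMatrix":
        base = dict(
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            scale=self.scale,
            matrix_type=self.matrix_type,
            setting=self.setting,
        )
        base.update(kwargs)
        return ExpressionMatrix(**base)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


@dataclass(frozen=True)
class ContrastDesign:
    """Sample-to-group assignment plus the two groups under comparison.

    The log2 fold-change sign convention downstream is group_a minus group_b.
    """

    group_of: Mapping[str, str]
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.contrast
        groups = list(self.group_of.values())
        for g in (a, b):
            if groups.count(g) < 2:
                raise ValueError(f"contrast group {g!r} needs >= 2 samples")

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]


@dataclass(frozen=True)
class WorkflowSpec:
    """One DEA workflow: (setting, matrix type, normalization, imputation, statistic)."""

    setting: str
    matrix_type: str
    normalization: str
    imputation: str
    dea: str

    def __str__(self) -> str:
        return f"{self.matrix_type}|{self.normalization}|{self.imputation}|{self.dea}"

    @classmethod
    def parse(cls, setting: str, text: str) -> "WorkflowSpec":
        """Parse a pipe-separated 4-tuple ``matrix|norm|impute|dea``."""
        parts = text.split("|")
        if len(parts) != 4:
            raise ValueError(f"expected 'matrix|norm|impute|dea', got {text!r}")
        return cls(setting, *parts)


@dataclass
class GroundTruth:
    """Spike-in truth: which proteins are differential and by how much."""

    is_de: Mapping[str, bool]
    true_log2fc: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(self.true_log2fc) - set(self.is_de)
        if missing:
            raise ValueError(f"log2fc given for unknown proteins: {sorted(missing)[:5]}")

    def covers(self, protein_ids: Sequence[str]) -> bool:
        return all(p in self.is_de for p in protein_ids)

    @property
    def proteins(self) -> list[str]:
        return list(self.is_de)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "na", "nan", "n/a", "null"}


def read_matrix(
    path,
    dialect: str = "tsv",
    matrix_type: str = "LFQ",
    setting: str = "generic",
    scale: str = "raw",
) -> ExpressionMatrix:
    """Read a wide protein x sample table.

    First column = protein IDs, header row = sample IDs. Empty/NA cells are
    missing; raw zeros are additionally mapped to missing for intensity-type
    matrices (spectral counts keep them).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise MatrixFormatError("matrix file needs a protein column and >= 1 sample")
    protein_ids = [str(p) for p in df.iloc[:, 0]]
    dupes = _duplicates(protein_ids)
    if dupes:
        raise MatrixFormatError(f"duplicate protein IDs: {sorted(dupes)}")
    sample_ids = [str(c) for c in df.columns[1:]]
    values = np.empty((len(protein_ids), len(sample_ids)))
    for j, col in enumerate(df.columns[1:]):
        for i, cell in enumerate(df[col]):
            token = str(cell).strip()
            if token.lower() in _NA_TOKENS:
                values[i, j] = MISSING
                continue
            try:
                values[i, j] = float(token)
            except ValueError:
                raise MatrixFormatError(
                    f"non-numeric cell {token!r} at protein {protein_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    if scale == "raw" and matrix_type not in COUNT_MATRIX_TYPES:
        values[values == 0] = MISSING
    return ExpressionMatrix(protein_ids, sample_ids, values, scale, matrix_type, setting)


def write_matrix(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write a matrix as read_matrix expects; missing cells become empty."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = matrix.to_frame()
    df.index.name = "protein"
    df.to_csv(path, sep=sep, na_rep="", float_format="%.12g")


def read_design(path) -> dict[str, str]:
    """Read a ``sample\\tgroup`` design table into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise MatrixFormatError("design table needs 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


def read_truth(path) -> GroundTruth:
    """Read a ``protein\\tis_de\\ttrue_log2fc`` table."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    is_de = {
        p: str(v).strip().lower() in {"1", "true", "t", "yes"}
        for p, v in zip(df["protein"], df["is_de"])
    }
    lfc = {p: float(v) for p, v in zip(df["protein"], df["true_log2fc"])}
    return GroundTruth(is_de=is_de, true_log2fc=lfc)


def write_truth(truth: GroundTruth, path) -> None:
    df = pd.DataFrame(
        {
            "protein": truth.proteins,
            "is_de": [int(truth.is_de[p]) for p in truth.proteins],
            "true_log2fc": [truth.true_log2fc[p] for p in truth.proteins],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_design(group_of: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(group_of), "group": list(group_of.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Contrast enumeration
# ---------------------------------------------------------------------------

def enumerate_contrasts(groups: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered group pairs, lexicographically ordered."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 group labels")
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be distinct")
    return sorted(tuple(sorted(pair)) for pair in combinations(labels, 2))


# ---------------------------------------------------------------------------
# Option registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Option:
    """A registered choice for one workflow step.

    ``available`` is False for plugin slots: options the registry knows by
    name but whose implementation must be supplied by the user.
    """

    name: str
    available: bool = True


_BUILTIN_NORMALIZATIONS = (
    "none", "center.mean", "center.median", "div.mean", "div.median",
    "total", "max", "quantiles", "quantiles.robust", "MBQN", "Rlr", "lossf",
)
_PLUGIN_NORMALIZATIONS = ("vsn",)

_BUILTIN_IMPUTATIONS = ("none", "zero", "min", "MinDet", "MinProb", "knn", "SeqKNN", "Impseq")
_PLUGIN_IMPUTATIONS = ("bpca", "mice", "missForest", "GMS", "QRILC", "MLE", "nbavg", "Impseqrob")

_BUILTIN_DEA = ("ttest", "anova", "modt")
_PLUGIN_DEA_INTENSITY = ("limma", "ROTS", "DEqMS", "proDA", "DEP", "MSstats", "SAM")
_PLUGIN_DEA_COUNTS = ("edgeR", "plgem", "beta_binomial")

#: DEA statistics that operate on spectral counts (everything else expects
#: log2 intensities).
COUNT_BASED_DEA = frozenset(_PLUGIN_DEA_COUNTS)

_MATRIX_BY_SETTING: Mapping[str, tuple[str, ...]] = {
    "FG_DDA": ("counts", "top0", "top3", "LFQ", "dlfq"),
    "MQ_DDA": ("counts", "top0", "top3", "LFQ", "dlfq"),
    "DIANN_DIA": ("top1", "top3", "LFQ", "dlfq"),
    "spt_DIA": ("top1", "top3", "LFQ", "dlfq"),
    "FG_TMT": ("abd", "ratio", "phi"),
    "MQ_TMT": ("reporter",),
    "generic": MATRIX_TYPES,
}


def _default_registry() -> dict[str, dict[str, list[Option]]]:
    reg: dict[str, dict[str, list[Option]]] = {}
    for setting in SETTINGS:
        dea: list[Option] = [Option(n) for n in _BUILTIN_DEA]
        dea += [Option(n, available=False) for n in _PLUGIN_DEA_INTENSITY]
        if "counts" in _MATRIX_BY_SETTING[setting]:
            dea += [Option(n, available=False) for n in _PLUGIN_DEA_COUNTS]
        reg[setting] = {
            "matrix": [Option(m) for m in _MATRIX_BY_SETTING[setting]],
            "normalization": [Option(n) for n in _BUILTIN_NORMALIZATIONS]
            + [Option(n, available=False) for n in _PLUGIN_NORMALIZATIONS],
            "imputation": [Option(n) for n in _BUILTIN_IMPUTATIONS]
            + [Option(n, available=False) for n in _PLUGIN_IMPUTATIONS],
            "dea": dea,
        }
    return reg


#: The shipped registry. Declarative and user-editable: mutate it (or build
#: your own) to reconstruct a different workflow grid.
REGISTRY: dict[str, dict[str, list[Option]]] = _default_registry()


def registry_options(setting: str, step: str, registry=None) -> list[Option]:
    """Registered options for one step of one quantification setting."""
    registry = REGISTRY if registry is None else registry
    if setting not in registry:
        raise RegistryError(f"unknown setting {setting!r}")
    if step not in registry[setting]:
        raise RegistryError(f"unknown step {step!r}")
    return list(registry[setting][step])


def validate_workflow(spec: WorkflowSpec, registry=None) -> list[str]:
    """Check a workflow against the registry and compatibility rules.

    Returns a list of violations; an empty list means the workflow is valid.
    """
    violations: list[str] = []
    registry = REGISTRY if registry is None else registry
    if spec.setting not in registry:
        return [f"unknown setting {spec.setting!r}"]
    for step, option in (
        ("matrix", spec.matrix_type),
        ("normalization", spec.normalization),
        ("imputation", spec.imputation),
        ("dea", spec.dea),
    ):
        names = {o.name for o in registry[spec.setting][step]}
        if option not in names:
            violations.append(
                f"{step} option {option!r} not registered for setting {spec.setting!r}"
            )
    if spec.dea in COUNT_BASED_DEA and spec.matrix_type not in COUNT_MATRIX_TYPES:
        violations.append(
            f"count-based statistic {spec.dea!r} requires a counts matrix, "
            f"got {spec.matrix_type!r}"
        )
    if spec.dea not in COUNT_BASED_DEA and spec.matrix_type in COUNT_MATRIX_TYPES:
        violations.append(
            f"intensity statistic {spec.dea!r} is incompatible with a counts matrix"
        )
    return violations


# ---------------------------------------------------------------------------
# Simple matrix queries / transforms
# ---------------------------------------------------------------------------

def missing_rate(matrix: ExpressionMatrix) -> float:
    """Fraction of missing cells."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    return float(np.isnan(matrix.values).mean())


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform a raw matrix; zeros in intensity matrices become missing."""
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2-scaled")
    values = matrix.values.copy()
    if matrix.matrix_type not in COUNT_MATRIX_TYPES:
        values[values == 0] = MISSING
    observed = ~np.isnan(values)
    if np.any(values[observed] < 0):
        raise ValueError("negative value in raw matrix")
    if matrix.matrix_type in COUNT_MATRIX_TYPES and np.any(values[observed] == 0):
        # counts keep zeros as observations; offset so log2 is defined
        values[observed] = np.log2(values[observed] + 1.0)
    else:
        values[observed] = np.log2(values[observed])
    return matrix.copy_with(values=values, scale="log2")


def strip_multi_protein_groups(
    protein_ids: Sequence[str], delimiter: str = PROTEIN_GROUP_DELIMITER
) -> list[str]:
    """Drop identifiers that name more than one protein."""
    return [p for p in protein_ids if delimiter not in p]
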