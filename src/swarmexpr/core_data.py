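"""Expression-matrix containers, delimited-text I/O and a seeded synthetic generator.

The study dataset this package targets is a two-class (tumour / normal) bulk
microarray experiment: a genes × samples matrix of fluorescence intensities
with 2000 genes and 62 samples (40 cancer, 22 normal).  Because the original
matrix is not redistributable, :func:`generate_synthetic_dataset` emulates its
shape and marginal statistics — strictly positive, right-skewed, heavy-tailed
intensities — from a log-normal model with block-constant gene correlation and
a configurable set of differentially expressed genes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CANCER",
    "NORMAL",
    "LABELS",
    "ExpressionDataset",
    "SyntheticSpec",
    "DataFormatError",
    "ValidationError",
    "load_expression_matrix",
    "write_expression_matrix",
    "generate_synthetic_dataset",
    "train_test_split",
]

#: Canonical class labels. Cancer is the positive class throughout the package.
CANCER = "cancer"
NORMAL = "normal"
LABELS = (CANCER, NORMAL)


class DataFormatError(ValueError):
    """Raised for malformed expression-matrix files (parse or structure)."""


class ValidationError(ValueError):
    """Raised when an argument violates a documented precondition."""


@dataclass
class ExpressionDataset:
    """A genes × samples intensity matrix with identifiers and binary labels.

    Attributes
    ----------
    values:
        ``(n_genes, n_samples)`` float array of intensities (arbitrary
        fluorescence units).
    gene_ids, sample_ids:
        Row / column identifiers, unique within each axis.
    labels:
        Per-sample class, each ``"cancer"`` or ``"normal"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.labels = list(self.labels)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes × samples matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise DataFormatError(
                f"row count {n_genes} != number of gene ids {len(self.gene_ids)}"
            )
        if n_samples != len(self.sample_ids) or n_samples != len(self.labels):
            raise DataFormatError(
                f"column count {n_samples} != sample ids "
                f"{len(self.sample_ids)} / labels {len(self.labels)}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataFormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample ids")
        bad = sorted(set(self.labels) - set(LABELS))
        if bad:
            raise DataFormatError(f"unknown labels {bad}; allowed: {LABELS}")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("intensities must be finite")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.label_array() == label)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic microarray generator.

    Defaults emulate the study dataset: 2000 genes, 40 cancer + 22 normal
    samples, with 50 differentially expressed genes shifted by 3.0 on the
    natural-log scale in the cancer class.  ``base_log_mean`` / ``base_log_sd``
    set the log-normal marginal (8.6 / 0.5 give a raw-scale mean near 6e3,
    skewness ≈ 1.8 and kurtosis ≈ 9 — right-skewed and heavy-tailed, like raw
    microarray intensities).  Genes are grouped in consecutive blocks of
    ``block_size`` sharing correlation ``block_rho`` on the log scale.
    """

    n_genes: int = 2000
    n_cancer: int = 40
    n_normal: int = 22
    n_informative: int = 50
    effect_size: float = 3.0
    base_log_mean: float = 8.6
    base_log_sd: float = 0.5
    block_size: int = 50
    block_rho: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.n_cancer < 1 or self.n_normal < 1:
            problems.append("n_cancer and n_normal must be >= 1")
        if not (0 <= self.n_informative <= self.n_genes):
            problems.append("n_informative must satisfy 0 <= n_informative <= n_genes")
        if self.effect_size < 0:
            problems.append("effect_size must be >= 0")
        if not (0 <= self.block_rho < 1):
            problems.append("block_rho must satisfy 0 <= block_rho < 1")
        if self.base_log_sd <= 0:
            problems.append("base_log_sd must be > 0")
        if self.block_size < 1:
            problems.append("block_size must be >= 1")
        if problems:
            raise ValidationError("invalid SyntheticSpec: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def load_expression_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
    label_source: str = "sidecar",
) -> ExpressionDataset:
    """Load a delimited expression matrix with class labels.

    Parameters
    ----------
    path:
        CSV/TSV file; the delimiter is sniffed from the header.  First column
        holds gene identifiers, the header row holds sample identifiers.
    orientation:
        ``"genes-in-rows"`` (the canonical layout) or ``"samples-in-rows"``
        (transposed on load).
    label_source:
        ``"sidecar"`` reads ``<path>.labels.tsv`` (sample_id <tab> class);
        ``"header-row"`` reads labels from a second header line starting with
        ``#labels``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataFormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        rows = [first.rstrip("\n").split(delim)]
        rows += [r for r in csv.reader(fh, delimiter=delim)]

    header = rows[0]
    col_ids = [c.strip() for c in header[1:]]
    body = rows[1:]

    labels_by_col: list[str] | None = None
    if body and body[0] and body[0][0].strip().lstrip("#").lower() in ("labels", "label"):
        labels_by_col = [c.strip() for c in body[0][1:]]
        body = body[1:]
    if label_source == "header-row" and labels_by_col is None:
        raise DataFormatError(f"{path}: label row requested but no '#labels' row found")

    row_ids = []
    values = np.empty((len(body), len(col_ids)), dtype=float)
    for i, row in enumerate(body):
        if len(row) != len(col_ids) + 1:
            raise DataFormatError(
                f"{path}: row {i + 1} ('{row[0] if row else ''}') has "
                f"{len(row) - 1} cells, expected {len(col_ids)}"
            )
        row_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric value '{cell.strip()}' at row id "
                    f"'{row[0].strip()}' (row {i + 1}), column id "
                    f"'{col_ids[j]}' (column {j + 1})"
                ) from None

    if orientation == "samples-in-rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
        # labels_by_col annotated the file's columns, i.e. genes — not allowed
        if labels_by_col is not None:
            raise DataFormatError(
                f"{path}: a '#labels' row is only valid for genes-in-rows files"
            )
    elif orientation != "genes-in-rows":
        raise ValidationError(f"unknown orientation '{orientation}'")

    gene_ids, sample_ids = row_ids, col_ids

    if labels_by_col is not None:
        labels = labels_by_col
    else:
        sidecar = path.with_name(path.name + ".labels.tsv")
        if not sidecar.exists():
            raise DataFormatError(f"label sidecar {sidecar} not found")
        mapping: dict[str, str] = {}
        with sidecar.open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                sid, _, lab = line.rstrip("\n").partition("\t")
                mapping[sid.strip()] = lab.strip()
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DataFormatError(
                f"{sidecar}: missing labels for samples {missing[:5]}"
            )
        labels = [mapping[s] for s in sample_ids]

    if len(labels) != len(sample_ids):
        raise DataFormatError(
            f"{path}: {len(labels)} labels for {len(sample_ids)} samples"
        )
    return ExpressionDataset(values, gene_ids, sample_ids, labels)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset as TSV (full float precision) plus a label sidecar.

    ``load_expression_matrix(write_expression_matrix(d, p))`` is an exact
    identity on values, identifiers and labels.
    """
    if dataset.n_samples == 0 or dataset.n_genes == 0:
        raise DataFormatError("refusing to write an empty dataset")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
        for gid, row in zip(dataset.gene_ids, dataset.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
    sidecar = path.with_name(path.name + ".labels.tsv")
    with sidecar.open("w") as fh:
        for sid, lab in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{sid}\t{lab}\n")
    return path


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

def generate_synthetic_dataset(spec: SyntheticSpec = SyntheticSpec()) -> ExpressionDataset:
    """Draw a synthetic two-class microarray dataset.

    The log-intensity of gene *g* in sample *s* is

    ``base_log_mean + effect·1[g informative, s cancer] + base_log_sd · z_gs``

    where ``z_gs = sqrt(rho)·u_bs + sqrt(1−rho)·e_gs`` shares the factor
    ``u_bs`` across the genes of block *b*, giving within-block correlation
    ``rho`` on the log scale.  Intensities are ``exp`` of that — strictly
    positive, right-skewed and heavy-tailed on the raw scale.  Output is
    bit-identical for identical specs (including the seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_cancer + spec.n_normal
    n_blocks = math.ceil(spec.n_genes / spec.block_size)

    block_factor = rng.standard_normal((n_blocks, n_samples))
    noise = rng.standard_normal((spec.n_genes, n_samples))
    block_of_gene = np.arange(spec.n_genes) // spec.block_size
    z = (
        math.sqrt(spec.block_rho) * block_factor[block_of_gene]
        + math.sqrt(1.0 - spec.block_rho) * noise
    )

    log_x = spec.base_log_mean + spec.base_log_sd * z
    if spec.n_informative and spec.effect_size:
        log_x[: spec.n_informative, : spec.n_cancer] += spec.effect_size

    labels = [CANCER] * spec.n_cancer + [NORMAL] * spec.n_normal
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    return ExpressionDataset(np.exp(log_x), gene_ids, sample_ids, labels)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def train_test_split(
    dataset: ExpressionDataset,
    train_fraction: float = 0.85,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into disjoint train/test sets.

    The per-class test count is ``floor((1 − train_fraction) · n_class)`` with
    the remainder to training, so counts are deterministic; for 40/22 samples
    at 0.85 this yields 53 train / 9 test.  Returns sorted index arrays whose
    union covers all samples.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    labels = dataset.label_array()

    if stratified:
        test_parts = []
        for label in LABELS:
            idx = np.flatnonzero(labels == label)
            if idx.size == 0:
                raise ValidationError(f"no samples of class '{label}'")
            n_test = int(math.floor((1.0 - train_fraction) * idx.size))
            perm = rng.permutation(idx)
            test_parts.append(perm[:n_test])
        test = np.sort(np.concatenate(test_parts)).astype(int)
    else:
        n_test = int(math.floor((1.0 - train_fraction) * n))
        test = np.sort(rng.permutation(n)[:n_test]).astype(int)

    train = np.setdiff1d(np.arange(n), test)
    if train.size == 0 or test.size == 0:
        raise ValidationError(
            f"train_fraction {train_fraction} leaves an empty partition "
            f"({train.size} train / {test.size} test of {n})"
        )
    return train, test
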