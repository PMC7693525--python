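"""Core container and I/O for qPCR Cq tables with non-detects.

A qPCR experiment yields one quantification cycle (Cq) per (gene, sample)
reaction; reactions that never cross the fluorescence threshold yield no Cq
value at all (*non-detects*).  :class:`QpcrDataset` carries the Cq matrix
together with the boolean detection matrix Z, the sample-type (replicate
group) partition, optional batch / control annotations, and the hard
detection limit S (default 40 cycles) beyond which detection is impossible.

Two non-detect encodings are accepted on input: a sentinel Cq equal to (or
exceeding) the detection limit, the convention used by most instrument
software, and an explicit missing value.  Internally non-detects are always
represented by ``detected == False``; their ``cq`` entries are NaN and are
ignored by every estimator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_DETECTION_LIMIT = 40.0

_LONG_COLUMNS = ("gene", "sample", "cq", "sample_type")


@dataclasses.dataclass
class QpcrDataset:
    """Genes x samples Cq matrix with detection indicators and annotations.

    Parameters
    ----------
    cq
        (G, N) float array of Cq values in cycles. Entries where
        ``detected`` is False are ignored (and stored as NaN after
        validation).
    detected
        (G, N) boolean matrix Z; True where a Cq value was observed.
    genes, samples
        Identifiers for the rows / columns.
    sample_type
        Length-N array mapping each sample to its replicate group.
    detection_limit
        Hard limit S (cycles); observed values >= S are coerced to
        non-detects by :meth:`validate`.
    batch
        Optional length-N batch labels (relative quantification).
    is_control
        Optional length-N booleans marking matched control samples.
    """

    cq: np.ndarray
    detected: np.ndarray
    genes: np.ndarray
    samples: np.ndarray
    sample_type: np.ndarray
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    batch: np.ndarray | None = None
    is_control: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        self.genes = np.asarray(self.genes, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.sample_type = np.asarray(self.sample_type, dtype=object)
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
        if self.is_control is not None:
            self.is_control = np.asarray(self.is_control, dtype=bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]

    @property
    def groups(self) -> np.ndarray:
        """Unique sample types, in order of first appearance."""
        _, idx = np.unique(self.sample_type, return_index=True)
        return self.sample_type[np.sort(idx)]

    def group_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (codes, groups) with codes[j] the group index of sample j."""
        groups = self.groups
        lookup = {g: i for i, g in enumerate(groups)}
        codes = np.array([lookup[t] for t in self.sample_type], dtype=int)
        return codes, groups

    # -- validation -----------------------------------------------------
    def validate(self, require_detected_per_group: bool = True) -> "QpcrDataset":
        """Coerce sentinel values and check structural invariants.

        Values at or above the detection limit are coerced to non-detects
        (the sentinel convention).  Validating an already-valid dataset is
        a no-op.  Raises :class:`ValidationError` when a (gene,
        sample-type) cell has zero detected replicates, since the model
        requires at least one observed value per cell.
        """
        if self.cq.shape != self.detected.shape:
            raise ValidationError(
                f"cq shape {self.cq.shape} != detected shape {self.detected.shape}"
            )
        if self.cq.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("cq shape does not match gene/sample labels")
        if len(self.sample_type) != self.n_samples:
            raise ValidationError("sample_type length does not match samples")
        over = self.detected & np.isfinite(self.cq) & (self.cq >= self.detection_limit)
        if over.any():
            logger.info("coercing %d values >= detection limit to non-detects", over.sum())
            self.detected = self.detected & ~over
        bad = self.detected & ~np.isfinite(self.cq)
        if bad.any():
            raise ValidationError("non-finite Cq value marked as detected")
        self.cq = np.where(self.detected, self.cq, np.nan)
        if require_detected_per_group:
            offenders = self.cells_without_detection()
            if offenders:
                raise ValidationError(
                    "every (gene, sample_type) needs >= 1 detected replicate; "
                    "all replicates are non-detects for: "
                    + ", ".join(f"({g}, {k})" for g, k in offenders[:20])
                )
        return self

    def cells_without_detection(self) -> list[tuple[str, str]]:
        """(gene, sample_type) cells in which every replicate is a non-detect."""
        codes, groups = self.group_codes()
        offenders = []
        for k, grp in enumerate(groups):
            cols = codes == k
            none = ~self.detected[:, cols].any(axis=1)
            offenders.extend((self.genes[i], grp) for i in np.nonzero(none)[0])
        return offenders

    # -- manipulation ---------------------------------------------------
    def copy(self) -> "QpcrDataset":
        return QpcrDataset(
            cq=self.cq.copy(),
            detected=self.detected.copy(),
            genes=self.genes.copy(),
            samples=self.samples.copy(),
            sample_type=self.sample_type.copy(),
            detection_limit=self.detection_limit,
            batch=None if self.batch is None else self.batch.copy(),
            is_control=None if self.is_control is None else self.is_control.copy(),
        )

    def subset(self, gene_mask=None, sample_mask=None) -> "QpcrDataset":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        return QpcrDataset(
            cq=self.cq[np.ix_(gm, sm)],
            detected=self.detected[np.ix_(gm, sm)],
            genes=self.genes[gm],
            samples=self.samples[sm],
            sample_type=self.sample_type[sm],
            detection_limit=self.detection_limit,
            batch=None if self.batch is None else self.batch[sm],
            is_control=None if self.is_control is None else self.is_control[sm],
        )

    def to_long(self, nondetect_encoding: str = "sentinel") -> pd.DataFrame:
        """Long-format table; non-detects as sentinel S or empty values."""
        g_idx, s_idx = np.meshgrid(np.arange(self.n_genes), np.arange(self.n_samples), indexing="ij")
        cq = self.cq.ravel().astype(object)
        det = self.detected.ravel()
        if nondetect_encoding == "sentinel":
            cq[~det] = self.detection_limit
        elif nondetect_encoding == "na":
            cq[~det] = np.nan
        else:
            raise ValueError(f"unknown nondetect_encoding {nondetect_encoding!r}")
        out = pd.DataFrame(
            {
                "gene": self.genes[g_idx.ravel()],
                "sample": self.samples[s_idx.ravel()],
                "cq": cq,
                "sample_type": self.sample_type[s_idx.ravel()],
            }
        )
        if self.batch is not None:
            out["batch"] = self.batch[s_idx.ravel()]
        if self.is_control is not None:
            out["is_control"] = self.is_control[s_idx.ravel()]
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _from_long(df: pd.DataFrame, nondetect_encoding: str, detection_limit: float) -> QpcrDataset:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"long table missing required columns: {missing}")
    dup = df.duplicated(subset=["gene", "sample"])
    if dup.any():
        rows = df.loc[dup, ["gene", "sample"]].iloc[0]
        raise ValidationError(f"duplicated (gene, sample) pair: ({rows['gene']}, {rows['sample']})")
    cq_raw = pd.to_numeric(df["cq"], errors="coerce")
    bad = cq_raw.isna() & df["cq"].notna() & (df["cq"].astype(str).str.strip() != "")
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(f"row {row}: could not parse cq value {df['cq'].iloc[row]!r}")

    genes = df["gene"].drop_duplicates().to_numpy()
    samples = df["sample"].drop_duplicates().to_numpy()
    wide = df.assign(cq=cq_raw).pivot(index="gene", columns="sample", values="cq")
    wide = wide.reindex(index=genes, columns=samples)
    if wide.isna().to_numpy().any() and nondetect_encoding == "sentinel":
        # sentinel files may still contain NA holes; treat them as non-detects
        logger.info("sentinel-encoded table contains NA entries; treated as non-detects")

    ann = df.drop_duplicates(subset="sample").set_index("sample").reindex(samples)
    cq = wide.to_numpy(dtype=float)
    detected = np.isfinite(cq)
    if nondetect_encoding == "sentinel":
        detected &= cq < detection_limit
    elif nondetect_encoding != "na":
        raise ValueError(f"unknown nondetect_encoding {nondetect_encoding!r}")
    ds = QpcrDataset(
        cq=cq,
        detected=detected,
        genes=genes,
        samples=samples,
        sample_type=ann["sample_type"].to_numpy(),
        detection_limit=detection_limit,
        batch=ann["batch"].to_numpy() if "batch" in ann.columns else None,
        is_control=ann["is_control"].astype(bool).to_numpy() if "is_control" in ann.columns else None,
    )
    return ds.validate()


def read_dataset(
    path,
    format: str = "long",
    nondetect_encoding: str = "sentinel",
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    annotations=None,
) -> QpcrDataset:
    """Read a validated :class:`QpcrDataset` from CSV.

    ``format="long"`` expects columns gene, sample, cq, sample_type and
    optionally batch / is_control.  ``format="wide"`` expects a genes x
    samples matrix (first column = gene names) plus a sidecar annotation
    CSV (``annotations``) with columns sample, sample_type[, batch,
    is_control].
    """
    path = Path(path)
    if format == "long":
        return _from_long(pd.read_csv(path), nondetect_encoding, detection_limit)
    if format == "wide":
        if annotations is None:
            raise ParseError("wide format requires a sidecar annotation table")
        mat = pd.read_csv(path, index_col=0)
        ann = pd.read_csv(annotations)
        if "sample" not in ann.columns or "sample_type" not in ann.columns:
            raise ParseError("annotation table must have sample and sample_type columns")
        ann = ann.set_index("sample").reindex(mat.columns)
        if ann["sample_type"].isna().any():
            missing = ann.index[ann["sample_type"].isna()][0]
            raise ValidationError(f"sample {missing!r} has no annotation row")
        cq = mat.to_numpy(dtype=float)
        detected = np.isfinite(cq)
        if nondetect_encoding == "sentinel":
            detected &= cq < detection_limit
        ds = QpcrDataset(
            cq=cq,
            detected=detected,
            genes=mat.index.to_numpy(),
            samples=mat.columns.to_numpy(),
            sample_type=ann["sample_type"].to_numpy(),
            detection_limit=detection_limit,
            batch=ann["batch"].to_numpy() if "batch" in ann.columns else None,
            is_control=ann["is_control"].astype(bool).to_numpy() if "is_control" in ann.columns else None,
        )
        return ds.validate()
    raise ValueError(f"unknown format {format!r}")


def write_dataset(ds: QpcrDataset, path, nondetect_encoding: str = "sentinel") -> None:
    """Write the long-CSV dialect understood by :func:`read_dataset`."""
    ds.to_long(nondetect_encoding).to_csv(path, index=False)


def write_imputed(ds: QpcrDataset, imps, path) -> list[Path]:
    """Write one long-format CSV per imputed dataset plus a JSON manifest.

    Each CSV carries an ``imputed`` column flagging cells that were
    non-detects in the input.  The manifest records M, the injected
    uncertainty sources, and the seed, so an imputation run can be traced.
    """
    if imps.m < 1 or not imps.completed:
        raise ValidationError("empty ImputationSet")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    base = ds.to_long(nondetect_encoding="na")
    flag = (~ds.detected).ravel()
    for m, mat in enumerate(imps.completed, start=1):
        df = base.copy()
        df["cq"] = np.asarray(mat, dtype=float).ravel()
        df["imputed"] = flag
        f = outdir / f"imputed_{m:03d}.csv"
        df.to_csv(f, index=False)
        files.append(f)
    manifest = {
        "m": imps.m,
        "sources": sorted(imps.sources),
        "seed": imps.seed,
        "detection_limit": ds.detection_limit,
        "files": [f.name for f in files],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return files


def normalize_to_reference(ds: QpcrDataset, reference_gene) -> QpcrDataset:
    """Subtract a fully-detected reference (housekeeping) gene per sample.

    Returns the dataset on the delta-Cq scale with the reference gene
    removed.  The detection limit is shifted to ``S - min(reference Cq)``
    so that every observed normalized value still lies below it.
    """
    idx = np.nonzero(ds.genes == reference_gene)[0]
    if idx.size == 0:
        raise ValidationError(f"reference gene {reference_gene!r} not in dataset")
    i = int(idx[0])
    if not ds.detected[i].all():
        raise ValidationError(
            f"reference gene {reference_gene!r} has non-detects; it must be fully observed"
        )
    ref = ds.cq[i]
    keep = np.ones(ds.n_genes, bool)
    keep[i] = False
    out = ds.subset(gene_mask=keep)
    out.cq = out.cq - ref[None, :]
    out.detection_limit = float(ds.detection_limit - ref.min())
    return out
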