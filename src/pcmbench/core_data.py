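"""Domain types, delimited-table I/O, label binarization and encoders.

The bioactivity table is a delimited text file (comma or tab, auto-detected
from the header) with columns ``compound_id``, ``fingerprint`` (an
881-character 0/1 string), ``protein_id``, ``sequence`` and
``log_activity`` (log10 of IC50/Ki/Kd).  Activities are binarized at a
threshold of 6 on the log scale (pActivity convention: higher = stronger
binding, so ``active <=> log_activity >= 6``).

Proteins are one-hot encoded over a 26-letter alphabet into a fixed
1499 x 26 matrix with *prepadding*: all zero rows come before the residue
rows, so a sequence of length L occupies the last L rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

FINGERPRINT_LENGTH = 881
MAX_SEQUENCE_LENGTH = 1499
ACTIVITY_THRESHOLD = 6.0

#: 26 one-hot channels: the 25 IUPAC extended amino-acid letters (the
#: standard 20 plus B, J, O, U, Z and X) and a final catch-all channel for
#: any unrecognized symbol.  Order is fixed and part of the encoding.
AMINO_ACID_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBJOUZX"
N_CHANNELS = len(AMINO_ACID_ALPHABET)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACID_ALPHABET)}

TABLE_COLUMNS = ("compound_id", "fingerprint", "protein_id", "sequence", "log_activity")


@dataclass(frozen=True)
class BioactivityRecord:
    """One ligand-target pair.

    ``log_activity`` is None for SMOTE-synthetic records, which carry the
    minority-class label they were generated for and ``synthetic=True``.
    """

    compound_id: str
    protein_id: str
    label: int  # 1 = active, 0 = inactive
    log_activity: float | None = None
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.synthetic and self.log_activity is not None:
            raise ValueError("synthetic records carry no log_activity")


@dataclass
class Dataset:
    """Records plus the compound fingerprint and protein sequence maps.

    Every record's identifiers must resolve in the maps and original
    (non-synthetic) records are unique per (compound_id, protein_id).
    """

    records: list[BioactivityRecord]
    fingerprints: dict[str, np.ndarray]
    sequences: dict[str, str]

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.compound_id not in self.fingerprints:
                raise ValueError(f"unresolved compound_id {rec.compound_id!r}")
            if rec.protein_id not in self.sequences:
                raise ValueError(f"unresolved protein_id {rec.protein_id!r}")
            if not rec.synthetic:
                key = (rec.compound_id, rec.protein_id)
                if key in seen:
                    raise ValueError(f"duplicate original pair {key}")
                seen.add(key)
        for cid, fp in self.fingerprints.items():
            validate_fingerprint(fp, cid)

    @property
    def protein_ids(self) -> list[str]:
        return sorted({r.protein_id for r in self.records})

    def records_by_protein(self) -> dict[str, list[BioactivityRecord]]:
        out: dict[str, list[BioactivityRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.protein_id, []).append(rec)
        return out


def validate_fingerprint(bits: np.ndarray, compound_id: str = "?") -> np.ndarray:
    bits = np.asarray(bits)
    if bits.shape != (FINGERPRINT_LENGTH,):
        raise ValueError(
            f"fingerprint of {compound_id!r} has shape {bits.shape}, "
            f"expected ({FINGERPRINT_LENGTH},)"
        )
    if not np.isin(bits, (0, 1)).all():
        raise ValueError(f"fingerprint of {compound_id!r} has non-binary entries")
    return bits


def binarize_activity(log_value: float, threshold: float = ACTIVITY_THRESHOLD) -> int:
    """Binary label from a log-scale binding value: active iff value >= threshold.

    The boundary value (exactly 6 by default) is labelled active.
    """
    if not np.isfinite(log_value):
        raise ValueError(f"non-finite activity value {log_value!r}")
    return int(log_value >= threshold)


def encode_protein(sequence: str) -> np.ndarray:
    """Prepadded one-hot encoding of an amino-acid sequence.

    Returns a (1499, 26) 0/1 matrix.  The first 1499 - L rows are all-zero
    padding; each residue row is one-hot over :data:`AMINO_ACID_ALPHABET`.
    Unknown symbols map to the catch-all last channel.  Sequences longer
    than 1499 are truncated from the front (keeping the C-terminus), with
    a warning.
    """
    sequence = sequence.upper()
    if len(sequence) > MAX_SEQUENCE_LENGTH:
        logger.warning(
            "sequence of length %d front-truncated to %d",
            len(sequence),
            MAX_SEQUENCE_LENGTH,
        )
        sequence = sequence[-MAX_SEQUENCE_LENGTH:]
    mat = np.zeros((MAX_SEQUENCE_LENGTH, N_CHANNELS), dtype=np.int8)
    offset = MAX_SEQUENCE_LENGTH - len(sequence)
    catch_all = N_CHANNELS - 1
    for i, aa in enumerate(sequence):
        j = _AA_INDEX.get(aa)
        if j is None:
            logger.warning("unknown residue symbol %r mapped to catch-all channel", aa)
            j = catch_all
        mat[offset + i, j] = 1
    return mat


def _detect_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    return ","


def read_bioactivity_table(path: str | Path, delimiter: str | None = None) -> Dataset:
    """Read a delimited bioactivity table into a validated :class:`Dataset`.

    Rows with an unparsable or non-finite activity, or a malformed
    fingerprint, are rejected and logged; a missing schema column is a hard
    error naming the column.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline().rstrip("\n")
        delim = delimiter or _detect_delimiter(header_line)
        header = header_line.split(delim)
        col = {name: i for i, name in enumerate(header)}
        for name in TABLE_COLUMNS:
            if name not in col:
                raise ValueError(f"missing required column {name!r} in {path}")
        records: list[BioactivityRecord] = []
        fingerprints: dict[str, np.ndarray] = {}
        sequences: dict[str, str] = {}
        n_rejected = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delim)
            try:
                cid = fields[col["compound_id"]]
                pid = fields[col["protein_id"]]
                fp_str = fields[col["fingerprint"]]
                seq = fields[col["sequence"]]
                raw = fields[col["log_activity"]]
                log_value = float(raw)
                label = binarize_activity(log_value)
                fp = np.frombuffer(fp_str.encode(), dtype=np.uint8) - ord("0")
                fp = validate_fingerprint(fp.astype(np.int8), cid)
            except (ValueError, IndexError) as exc:
                n_rejected += 1
                logger.warning("rejected row %d of %s: %s", lineno, path, exc)
                continue
            records.append(
                BioactivityRecord(
                    compound_id=cid, protein_id=pid, label=label, log_activity=log_value
                )
            )
            fingerprints[cid] = fp
            sequences[pid] = seq
    if n_rejected:
        logger.info("%s: %d rows rejected", path, n_rejected)
    ds = Dataset(records=records, fingerprints=fingerprints, sequences=sequences)
    ds.validate()
    return ds


def write_bioactivity_table(dataset: Dataset, path: str | Path, delimiter: str = ",") -> None:
    """Write the original (non-synthetic) records of a Dataset as a table.

    Inverse of :func:`read_bioactivity_table` on valid datasets.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(TABLE_COLUMNS) + "\n")
        for rec in dataset.records:
            if rec.synthetic:
                continue
            fp = dataset.fingerprints[rec.compound_id]
            fh.write(
                delimiter.join(
                    (
                        rec.compound_id,
                        "".join(map(str, fp.tolist())),
                        rec.protein_id,
                        dataset.sequences[rec.protein_id],
                        repr(rec.log_activity),
                    )
                )
                + "\n"
            )
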