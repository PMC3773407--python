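"""Genome barcodes: per-fragment 4-mer-class frequency profiles.

A genome is cut into non-overlapping fragments of ``L`` bp (default 1000; the
trailing partial fragment is discarded, so N = floor(M/L)).  Each fragment is
summarised by the combined frequency of each 4-mer and its reverse
complement.  Pairing the 256 4-mers with their reverse complements yields 120
two-member classes plus 16 palindromic classes = 136 canonical classes, so a
genome becomes an N x 136 matrix.  Because the pairing is strand-symmetric,
the barcode of a genome equals the barcode of its reverse complement (with
fragment order reversed).

Compositionally anomalous fragments - candidates for foreign origin such as
horizontally transferred segments or phage insertions - stand out as rows far
from the genome's average barcode.  The per-genome "genomic evolution" value
aggregates this: r_ge = mean(dis) + 3*sd(dis) over the per-fragment Euclidean
distances to the average barcode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .genome_model import AnnotatedGenome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _build_classes(k: int = 4) -> tuple[list[str], np.ndarray]:
    """Canonical k-mer classes and the 4**k -> class index lookup table."""
    bases = "ACGT"
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in bases]
    canon_of = {}
    labels = []
    for mer in kmers:
        rc = _revcomp(mer)
        key = min(mer, rc)
        if key not in canon_of:
            canon_of[key] = None
    for key in sorted(canon_of):
        canon_of[key] = len(labels)
        labels.append(f"{key}|{_revcomp(key)}")
    lut = np.empty(len(kmers), dtype=np.int64)
    for i, mer in enumerate(kmers):
        lut[i] = canon_of[min(mer, _revcomp(mer))]
    return labels, lut


#: canonical 4-mer class labels, e.g. "AAAA|TTTT"; exactly 136 entries
CLASS_LABELS, _CLASS_LUT = _build_classes(4)
N_CLASSES = len(CLASS_LABELS)


class BarcodeError(ValueError):
    pass


@dataclass
class BarcodeMatrix:
    """N x 136 matrix of 4-mer-class frequencies for one genome."""

    genome_id: str
    L: int
    k: int
    values: np.ndarray  # shape (N, 136)

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]


@dataclass
class AnomalyProfile:
    """Average barcode, per-fragment anomaly distances and r_ge for a genome."""

    genome_id: str
    L: int
    avg_barcode: np.ndarray  # (136,)
    dis: np.ndarray          # (N,)

    @property
    def r_ge(self) -> float:
        """Genomic evolution value: mean(dis) + 3 * sample sd(dis)."""
        return float(np.mean(self.dis) + 3.0 * np.std(self.dis, ddof=1))

    @property
    def n_fragments(self) -> int:
        return self.dis.shape[0]


def compute_barcode(
    genome: Union[AnnotatedGenome, str], L: int = 1000, k: int = 4
) -> BarcodeMatrix:
    """Compute the fragment x class frequency matrix.

    Each fragment contributes L-k+1 sliding windows; windows containing
    non-ACGT characters are excluded from both numerator and denominator, so
    rows of fully unambiguous fragments sum to exactly 1.
    """
    if k != 4:
        raise BarcodeError("only k=4 (136 classes) is supported")
    if isinstance(genome, AnnotatedGenome):
        if genome.sequence is None:
            raise BarcodeError(f"genome {genome.id!r} has no sequence")
        seq, gid = genome.sequence, genome.id
    else:
        seq, gid = genome, "<sequence>"
    m = len(seq)
    n_frag = m // L
    if n_frag < 1:
        raise BarcodeError(f"sequence length {m} shorter than fragment length {L}")

    codes = np.full(m, -1, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, code in zip(b"ACGT", range(4)):
        codes[arr == base] = code

    values = np.zeros((n_frag, N_CLASSES), dtype=np.float64)
    for i in range(n_frag):
        frag = codes[i * L : (i + 1) * L]
        # word index of each window; invalid if any constituent base is ambiguous
        windows = (
            frag[: L - k + 1] * 64 + frag[1 : L - k + 2] * 16
            + frag[2 : L - k + 3] * 4 + frag[3 : L - k + 4]
        )
        valid = (
            (frag[: L - k + 1] >= 0) & (frag[1 : L - k + 2] >= 0)
            & (frag[2 : L - k + 3] >= 0) & (frag[3 : L - k + 4] >= 0)
        )
        words = windows[valid]
        if words.size == 0:
            continue
        counts = np.bincount(_CLASS_LUT[words], minlength=N_CLASSES)
        values[i] = counts / words.size
    return BarcodeMatrix(genome_id=gid, L=L, k=k, values=values)


def anomaly_profile(bm: BarcodeMatrix) -> AnomalyProfile:
    """Average barcode and per-fragment Euclidean anomaly distances."""
    if bm.n_fragments < 2:
        raise BarcodeError(
            f"genome {bm.genome_id!r}: need >= 2 fragments for an anomaly "
            "profile (sd undefined otherwise)"
        )
    avg = bm.values.mean(axis=0)
    dis = np.sqrt(((bm.values - avg) ** 2).sum(axis=1))
    return AnomalyProfile(genome_id=bm.genome_id, L=bm.L, avg_barcode=avg, dis=dis)


def abnormal_fragments(profile: AnomalyProfile) -> np.ndarray:
    """Fragment indices sorted by anomaly distance descending, ties by
    ascending index (deterministic)."""
    idx = np.arange(profile.n_fragments)
    order = np.lexsort((idx, -profile.dis))
    return idx[order]


def write_barcode_tsv(bm: BarcodeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\t" + "\t".join(CLASS_LABELS) + "\n")
        for i, row in enumerate(bm.values):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
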