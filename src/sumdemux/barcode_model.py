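"""Barcode vocabularies, read layouts, and barcode error correction.

The assay attaches two barcodes to every molecule: a *sample index*
introduced in bulk (Tn5-loaded oligo for ATAC, barcoded oligo-dT for RNA)
and a *droplet barcode* added during microfluidic encapsulation.  The pair
``(sample label, droplet barcode)`` — a :class:`CellKey` — identifies one
nucleus even when several nuclei share a droplet, and is the join key
between the two modalities.

This module is deliberately free of any I/O on reads; it defines where the
barcode elements live in the raw reads (:class:`ReadLayout`), extracts them
(:func:`extract_elements`), and error-corrects them against whitelists
(:func:`correct_barcode`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "BarcodeWhitelist",
    "Segment",
    "ReadLayout",
    "CellKey",
    "BarcodeCall",
    "ReadTruncatedError",
    "extract_elements",
    "correct_barcode",
    "resolve_cell_key",
    "random_whitelist",
    "ATAC_LAYOUT",
    "RNA_LAYOUT",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# Statuses a barcode call can end in.  `spacer_fail` is set by the demux
# driver when a constant spacer segment does not match its expected sequence.
STATUS_EXACT = "exact"
STATUS_CORRECTED = "corrected"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_MATCH = "no_match"
STATUS_SPACER_FAIL = "spacer_fail"


class ReadTruncatedError(ValueError):
    """A source read is shorter than the layout requires."""


class CellKey(NamedTuple):
    """The (sample label, droplet barcode) pair that defines one nucleus."""

    sample_label: str
    droplet_barcode: str

    def __str__(self) -> str:  # fragments-file cell column
        return f"{self.sample_label}:{self.droplet_barcode}"

    @classmethod
    def parse(cls, text: str) -> "CellKey":
        sample, _, bc = text.rpartition(":")
        if not sample or not bc:
            raise ValueError(f"not a cell key: {text!r}")
        return cls(sample, bc)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE_TABLE), dtype=np.uint8)


# translate bytes A/C/G/T/N -> 0..4, everything else -> 4 (mismatch-to-all)
_ENCODE_TABLE = bytes(
    _BASE_CODE.get(chr(b), 4) if chr(b) in _BASE_CODE else 4 for b in range(256)
)


@dataclass
class BarcodeWhitelist:
    """A fixed-length barcode vocabulary for one barcode role.

    For correction with ``max_dist = d`` to be unambiguous the pairwise
    Hamming distance between entries should exceed ``2 d``; the constructor
    warns when that is violated (correction still works, but ties become
    possible and are rejected as ambiguous).
    """

    label: str
    entries: tuple[str, ...]
    modality: str  # "ATAC", "RNA" or "droplet"

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        if not entries:
            raise ValueError("whitelist is empty")
        lengths = {len(e) for e in entries}
        if len(lengths) != 1:
            raise ValueError(f"whitelist {self.label!r}: entries of unequal length")
        if len(set(entries)) != len(entries):
            raise ValueError(f"whitelist {self.label!r}: duplicate entries")
        bad = [e for e in entries if set(e) - set("ACGT")]
        if bad:
            raise ValueError(f"whitelist {self.label!r}: non-ACGT entry {bad[0]!r}")
        self.entries = entries
        self._matrix = np.vstack([_encode(e) for e in entries])
        self._index = {e: i for i, e in enumerate(entries)}
        self._corrector_cache: dict[int, dict[str, "BarcodeCall"]] = {}

    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def min_pairwise_distance(self) -> int:
        m = self._matrix
        best = m.shape[1]
        for i in range(len(m) - 1):
            d = int((m[i + 1 :] != m[i]).sum(axis=1).min())
            best = min(best, d)
        return best

    def validate_for_correction(self, max_dist: int) -> bool:
        """Warn (and return False) if entries are too close for ``max_dist``."""
        if len(self.entries) < 2:
            return True
        d = self.min_pairwise_distance()
        if d <= 2 * max_dist:
            warnings.warn(
                f"whitelist {self.label!r}: min pairwise Hamming distance {d} "
                f"<= 2*max_dist ({2 * max_dist}); correction may be ambiguous",
                stacklevel=2,
            )
            return False
        return True

    @classmethod
    def from_file(cls, path, label: str, modality: str) -> "BarcodeWhitelist":
        with open(path) as fh:
            entries = tuple(line.strip() for line in fh if line.strip())
        return cls(label=label, entries=entries, modality=modality)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.entries) + "\n")


@dataclass(frozen=True)
class BarcodeCall:
    """Outcome of matching one observed barcode against a whitelist."""

    observed: str
    corrected: Optional[str]  # None encodes MISS
    distance: int
    status: str

    @property
    def ok(self) -> bool:
        return self.corrected is not None


_MISS_TEMPLATE = dict(corrected=None, distance=-1)


def correct_barcode(
    observed: str, whitelist: BarcodeWhitelist, max_dist: int
) -> BarcodeCall:
    """Match ``observed`` to the unique whitelist entry within ``max_dist``.

    ``N`` bases mismatch every base, so a barcode with more than ``max_dist``
    Ns can never be rescued.  Ties at the minimum qualifying distance are
    rejected (``status="ambiguous"``) rather than broken arbitrarily.

    Raises
    ------
    ValueError
        If ``observed`` does not have the whitelist's length — that is a
        configuration error, not a per-read condition.
    """
    if len(observed) != whitelist.length:
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist length "
            f"{whitelist.length} (whitelist {whitelist.label!r})"
        )
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")

    if observed in whitelist._index:
        return BarcodeCall(observed, observed, 0, STATUS_EXACT)

    cache = whitelist._corrector_cache.setdefault(max_dist, {})
    hit = cache.get(observed)
    if hit is not None:
        return hit

    dists = (whitelist._matrix != _encode(observed)).sum(axis=1)
    dmin = int(dists.min())
    if dmin > max_dist:
        call = BarcodeCall(observed, None, -1, STATUS_NO_MATCH)
    elif int((dists == dmin).sum()) > 1:
        call = BarcodeCall(observed, None, -1, STATUS_AMBIGUOUS)
    else:
        best = whitelist.entries[int(dists.argmin())]
        call = BarcodeCall(observed, best, dmin, STATUS_CORRECTED)
    cache[observed] = call
    return call


# ---------------------------------------------------------------------------
# read layouts


_ROLES = {"sample_index", "spacer", "umi", "droplet_barcode", "payload"}
_SOURCES = {"R1", "R2", "I1", "I2"}


@dataclass(frozen=True)
class Segment:
    source_read: str  # R1 / R2 / I1 / I2
    start: int  # 0-based offset within the source read
    length: int
    role: str

    def __post_init__(self) -> None:
        if self.source_read not in _SOURCES:
            raise ValueError(f"unknown source read {self.source_read!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")
        if self.start < 0 or self.length <= 0:
            raise ValueError("segment start must be >= 0 and length > 0")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ReadLayout:
    """Declarative map of where each barcode element lives in the raw reads."""

    modality: str  # "ATAC" or "RNA"
    segments: tuple[Segment, ...]
    expected_spacer: str = ""

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, Segment) else Segment(**s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        by_role: dict[str, int] = {}
        for s in segs:
            by_role[s.role] = by_role.get(s.role, 0) + 1
        if by_role.get("droplet_barcode", 0) != 1:
            raise ValueError("layout must declare exactly one droplet_barcode segment")
        if by_role.get("sample_index", 0) != 1:
            raise ValueError("layout must declare exactly one sample_index segment")
        n_umi = by_role.get("umi", 0)
        if self.modality == "RNA" and n_umi != 1:
            raise ValueError("RNA layout must declare exactly one umi segment")
        if self.modality == "ATAC" and n_umi != 0:
            raise ValueError("ATAC layout must not declare a umi segment")
        # no overlaps within one source read
        for src in _SOURCES:
            spans = sorted(
                (s.start, s.end) for s in segs if s.source_read == src
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping segments in {src}")

    def segment(self, role: str) -> Segment:
        for s in self.segments:
            if s.role == role:
                return s
        raise KeyError(role)

    @property
    def umi_length(self) -> int:
        return self.segment("umi").length if self.modality == "RNA" else 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReadLayout":
        return cls(
            modality=d["modality"],
            segments=tuple(Segment(**s) for s in d["segments"]),
            expected_spacer=d.get("expected_spacer", "") or "",
        )

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "expected_spacer": self.expected_spacer,
            "segments": [
                {
                    "source_read": s.source_read,
                    "start": s.start,
                    "length": s.length,
                    "role": s.role,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_yaml(cls, path, name: str) -> "ReadLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc[name])


def extract_elements(
    reads: Mapping[str, str], layout: ReadLayout
) -> dict[str, object]:
    """Slice every declared segment out of one read quadruple.

    ``reads`` maps source-read names (``R1``/``R2``/``I1``/``I2``) to their
    sequences.  Returns a dict mapping each singleton role to its substring;
    payload segments (there may be several) are returned as a list under
    ``"payload"``.  No correction is applied here.

    Raises :class:`ReadTruncatedError` when a source read is shorter than the
    last segment it hosts; the caller rejects the record with reason
    ``"truncated"``.
    """
    out: dict[str, object] = {}
    payload: list[str] = []
    for seg in layout.segments:
        src = reads.get(seg.source_read)
        if src is None or len(src) < seg.end:
            raise ReadTruncatedError(
                f"{seg.source_read} shorter than layout segment "
                f"[{seg.start},{seg.end}) for role {seg.role}"
            )
        piece = src[seg.start : seg.end]
        if seg.role == "payload":
            payload.append(piece)
        else:
            out[seg.role] = piece
    if payload:
        out["payload"] = payload
    return out


def resolve_cell_key(
    sample_call: BarcodeCall,
    droplet_call: BarcodeCall,
    sample_map: Mapping[str, str],
) -> Optional[CellKey]:
    """Combine the two barcode calls into a :class:`CellKey`.

    Several index sequences may map to the same sample label (e.g. two RT
    primers per condition); the mapping collapses them.  Returns ``None``
    (MISS) when either call failed.
    """
    if not sample_call.ok or not droplet_call.ok:
        return None
    sample = sample_map.get(sample_call.corrected)
    if sample is None:
        raise KeyError(
            f"sample map does not cover whitelist entry {sample_call.corrected!r}"
        )
    return CellKey(sample, droplet_call.corrected)


def read_sample_map(path) -> dict[str, str]:
    """Two-column TSV: index sequence, sample label."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq, label = line.split("\t")[:2]
            out[seq] = label
    return out


def write_sample_map(sample_map: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for seq, label in sample_map.items():
            fh.write(f"{seq}\t{label}\n")


def random_whitelist(
    n: int,
    length: int,
    min_dist: int,
    rng: np.random.Generator,
    label: str = "whitelist",
    modality: str = "droplet",
    max_tries: int = 10_000,
) -> BarcodeWhitelist:
    """Draw ``n`` random barcodes with pairwise Hamming distance >= ``min_dist``.

    Greedy rejection sampling; raises if the space cannot be filled within
    ``max_tries`` consecutive rejections (never an issue at the sizes used
    here: 4^16 vastly exceeds any droplet whitelist).
    """
    accepted = np.empty((n, length), dtype=np.int64)
    n_acc = 0
    entries: list[str] = []
    bases = np.array(list("ACGT"))
    tries = 0
    while n_acc < n:
        cand = rng.integers(0, 4, size=length)
        if n_acc:
            d = (accepted[:n_acc] != cand).sum(axis=1).min()
            if d < min_dist:
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        f"could not build whitelist of {n} length-{length} "
                        f"barcodes at min_dist={min_dist}"
                    )
                continue
        tries = 0
        accepted[n_acc] = cand
        n_acc += 1
        entries.append("".join(bases[cand]))
    return BarcodeWhitelist(label=label, entries=tuple(entries), modality=modality)


# ---------------------------------------------------------------------------
# default layouts
#
# The sequenced cycle structure is: ATAC R1=55, I1=11, I2=16, R2=55;
# RNA R1=95, I1=6, I2=16, R2=21.  The droplet barcode is the 16-nt i5 (I2)
# in both modalities.  The ATAC sample index is read as the 11-nt I1; the
# RNA sample index plus UMI occupy the 21-nt R2 (11 + 10).  The exact oligo
# splits are configurable; these defaults are assumptions documented in the
# methods note.

ATAC_LAYOUT = ReadLayout(
    modality="ATAC",
    segments=(
        Segment("I1", 0, 11, "sample_index"),
        Segment("I2", 0, 16, "droplet_barcode"),
        Segment("R1", 0, 55, "payload"),
        Segment("R2", 0, 55, "payload"),
    ),
)

RNA_LAYOUT = ReadLayout(
    modality="RNA",
    segments=(
        Segment("I2", 0, 16, "droplet_barcode"),
        Segment("R2", 0, 11, "sample_index"),
        Segment("R2", 11, 10, "umi"),
        Segment("R1", 0, 95, "payload"),
    ),
)

DEFAULT_LAYOUTS = {"ATAC": ATAC_LAYOUT, "RNA": RNA_LAYOUT}

# demux mismatch tolerances: one mismatch on the ATAC sample index, two on
# the RNA sample index, one on the droplet barcode.
DEFAULT_MAX_DIST = {"ATAC_sample": 1, "RNA_sample": 2, "droplet": 1}
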