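"""Reading, writing and slicing annotated mitochondrial genomes.

A mitogenome is held as a plain (+)-strand DNA string plus an ordered list
of gene features. Internally every interval is 0-based half-open on the
(+) strand; GenBank and feature-table I/O convert from/to the 1-based
inclusive convention. On circular genomes a feature may wrap the origin,
which is encoded as ``start > end`` and normalized only when the sequence
is extracted.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("mitoarch")

PCG_LABELS = (
    "cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4l",
    "nad5", "nad6", "atp6", "atp8", "cytB",
)
RRNA_LABELS = ("rrnS", "rrnL")
TRNA_AA = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L1": "Leu", "L2": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S1": "Ser", "S2": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}
TRNA_LABELS = tuple("trn" + x for x in TRNA_AA)

KINDS = ("PCG", "tRNA", "rRNA", "CR", "spacer")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# canonical gene labels
# ---------------------------------------------------------------------------

# deposited records use many spellings; map the common synonyms onto the
# canonical label set used throughout the package
_SYNONYMS = {
    "coi": "cox1", "co1": "cox1", "coxi": "cox1", "cox1": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2", "cox2": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3", "cox3": "cox3",
    "nd1": "nad1", "nad1": "nad1", "nd2": "nad2", "nad2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nd4": "nad4", "nad4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nd5": "nad5", "nad5": "nad5",
    "nd6": "nad6", "nad6": "nad6",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "cytb": "cytB", "cob": "cytB", "cyb": "cytB",
    "12s": "rrnS", "rrns": "rrnS", "srrna": "rrnS", "12srrna": "rrnS",
    "16s": "rrnL", "rrnl": "rrnL", "lrrna": "rrnL", "16srrna": "rrnL",
    "dloop": "CR", "d-loop": "CR", "cr": "CR", "controlregion": "CR",
    "spacer": "spacer",
}

_AA3_TO_1 = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F", "gly": "G",
    "his": "H", "ile": "I", "lys": "K", "leu": "L", "met": "M", "asn": "N",
    "pro": "P", "gln": "Q", "arg": "R", "ser": "S", "thr": "T", "val": "V",
    "trp": "W", "tyr": "Y",
}

# anticodon-based disambiguation of the two Leu and two Ser isoacceptors:
# trnL1 = Leu(CUN), trnL2 = Leu(UUR); trnS1 = Ser(AGN), trnS2 = Ser(UCN)
_LEU_SER_BY_ANTICODON = {
    ("L", "TAG"): "L1", ("L", "TAA"): "L2",
    ("S", "TCT"): "S1", ("S", "GCT"): "S1", ("S", "TGA"): "S2",
}
_LEU_SER_BY_CODON_CLASS = {
    ("L", "CUN"): "L1", ("L", "CTN"): "L1", ("L", "UUR"): "L2", ("L", "TTR"): "L2",
    ("S", "AGN"): "S1", ("S", "AGY"): "S1", ("S", "UCN"): "S2", ("S", "TCN"): "S2",
}


def canonical_label(raw: str, anticodon: Optional[str] = None) -> str:
    """Map a raw gene name from an annotation onto the canonical label set.

    Unknown names are preserved verbatim (with a warning from callers that
    care). ``anticodon`` disambiguates trnL1/L2 and trnS1/S2.
    """
    name = raw.strip()
    key = re.sub(r"[\s_\-]+", "", name.lower())
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = re.match(r"^trna?[\-]?([a-z]{3}|[a-z])([0-9]?)(?:\(([a-z]{3})\))?$",
                 re.sub(r"[\s_]+", "", name.lower()))
    if m:
        aa_raw, idx, cls = m.groups()
        aa = _AA3_TO_1.get(aa_raw, aa_raw.upper() if len(aa_raw) == 1 else None)
        if aa is not None:
            if aa in ("L", "S"):
                sub = None
                if idx in ("1", "2"):
                    sub = aa + idx
                elif anticodon:
                    sub = _LEU_SER_BY_ANTICODON.get((aa, anticodon.upper().replace("U", "T")))
                elif cls:
                    sub = _LEU_SER_BY_CODON_CLASS.get((aa, cls.upper()))
                if sub:
                    return "trn" + sub
                return "trn" + aa  # ambiguous isoacceptor, left undisambiguated
            return "trn" + aa
    return name


def label_kind(label: str) -> Optional[str]:
    if label in PCG_LABELS:
        return "PCG"
    if label in RRNA_LABELS:
        return "rRNA"
    if label.startswith("trn"):
        return "tRNA"
    if label == "CR":
        return "CR"
    if label == "spacer":
        return "spacer"
    return None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the (+) strand coordinate system.

    ``start > end`` encodes a feature wrapping the origin of a circular
    genome. ``copy_index`` distinguishes duplicated genes with the same
    label (1 for the first/only copy).
    """

    label: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    copy_index: int = 1
    anticodon: Optional[str] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.label, self.copy_index)


@dataclass
class MitoGenome:
    """A (possibly circular) mitochondrial genome with ordered annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        for f in self.features:
            self._check_feature(f)
        self.features.sort(key=lambda f: (f.start, f.end))

    def _check_feature(self, f: GeneFeature) -> None:
        n = len(self)
        if not (0 <= f.start < n) or not (0 <= f.end <= n):
            raise ValueError(f"feature {f.label} [{f.start},{f.end}) outside genome of length {n}")
        if f.wraps and not self.circular:
            raise ValueError(f"wrap-around feature {f.label} on a linear genome")
        if f.start == f.end:
            raise ValueError(f"empty feature {f.label}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def add_feature(self, f: GeneFeature) -> None:
        self._check_feature(f)
        self.features.append(f)
        self.features.sort(key=lambda x: (x.start, x.end))

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def feature(self, label: str, copy_index: int = 1) -> GeneFeature:
        for f in self.features:
            if f.label == label and f.copy_index == copy_index:
                return f
        raise KeyError(f"no feature {label} (copy {copy_index}) in {self.id}")


def gene_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-sense sequence of a feature.

    (+)-strand features are plain slices; (−)-strand features are reverse
    complemented; wrap-around features on circular genomes are the
    suffix+prefix concatenation.
    """
    if feature not in genome.features:
        raise ValueError(f"feature {feature.label} does not belong to genome {genome.id}")
    if feature.wraps:
        plus = genome.sequence[feature.start:] + genome.sequence[:feature.end]
    else:
        plus = genome.sequence[feature.start:feature.end]
    return revcomp(plus) if feature.strand == "-" else plus


# ---------------------------------------------------------------------------
# GenBank I/O (Biopython-backed)
# ---------------------------------------------------------------------------

_GB_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR",
            "misc_feature": "spacer"}


def _feature_name(sf: SeqFeature) -> Optional[str]:
    for q in ("gene", "product", "note", "standard_name"):
        if q in sf.qualifiers:
            return str(sf.qualifiers[q][0])
    return None


def read_genbank(path) -> MitoGenome:
    """Read one annotated mitogenome from a GenBank flat file.

    Gene labels are canonicalized; unknown labels are preserved verbatim
    with a warning and the kind inferred from the feature key. GenBank
    coordinates (1-based inclusive) become 0-based half-open; a compound
    join over the origin becomes a wrap-around feature.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    circular = record.annotations.get("topology", "linear") == "circular"
    n = len(record.seq)
    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for sf in record.features:
        if sf.type not in _GB_KIND:
            continue
        if sf.type == "misc_feature":
            name = (_feature_name(sf) or "").lower()
            if "control" not in name and "d-loop" not in name:
                continue
        if sf.type == "D-loop" or sf.type == "misc_feature":
            raw = "CR"
        else:
            raw = _feature_name(sf)
            if raw is None:
                continue
        anticodon = None
        if "anticodon" in sf.qualifiers:
            m = re.search(r"seq:([acgtu]{3})", str(sf.qualifiers["anticodon"][0]), re.I)
            if m:
                anticodon = m.group(1).upper().replace("U", "T")
        label = canonical_label(raw, anticodon)
        kind = label_kind(label) or _GB_KIND[sf.type]
        if label_kind(label) is None:
            warnings.warn(f"unknown gene label {raw!r} kept verbatim (kind {kind})")
        if label == "CR":
            kind = "CR"
        loc = sf.location
        strand = "-" if loc.strand == -1 else "+"
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # join(x..N,1..y) over the origin of a circular record
            if (len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == n
                    and circular):
                start, end = int(parts[1].start), int(parts[0].end)
            else:
                start, end = int(loc.start), int(loc.end)
        else:
            start, end = int(loc.start), int(loc.end)
        seen[label] = seen.get(label, 0) + 1
        features.append(GeneFeature(label=label, kind=kind, start=start, end=end,
                                    strand=strand, copy_index=seen[label],
                                    anticodon=anticodon))
    return MitoGenome(id=record.id.split(".")[0] or record.name,
                      sequence=str(record.seq), circular=circular,
                      features=features)


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a MitoGenome as a GenBank flat file (inverse of read_genbank)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="mitochondrial genome",
                       annotations={"molecule_type": "DNA",
                                    "topology": "circular" if genome.circular else "linear"})
    kind_to_type = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                    "CR": "D-loop", "spacer": "misc_feature"}
    n = len(genome)
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation([FeatureLocation(f.start, n, strand),
                                    FeatureLocation(0, f.end, strand)])
        else:
            loc = FeatureLocation(f.start, f.end, strand)
        quals = {"gene": [f.label]}
        if f.kind == "CR":
            quals = {"note": [f"control region ({f.label})"]}
        if f.anticodon is not None:
            quals["anticodon"] = [f"(pos:complement(0..0),aa:Xxx,seq:{f.anticodon.lower()})"]
        record.features.append(SeqFeature(loc, type=kind_to_type[f.kind], qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + feature-table I/O
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("label", "kind", "start", "end", "strand", "copy_index")


def read_feature_table(fasta, table, circular: bool = True) -> MitoGenome:
    """Read a genome from a single-record FASTA plus a TSV feature table.

    The table has columns ``label kind start end strand copy_index``
    (header optional; coordinates 1-based inclusive; ``start > end`` means
    a wrap-around feature on a circular genome).
    """
    record = SeqIO.read(str(fasta), "fasta")
    n = len(record.seq)
    features: list[GeneFeature] = []
    keys: set[tuple] = set()
    with open(table) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "label":
                continue
            if len(parts) < 5:
                raise ValueError(f"{table}:{lineno}: expected ≥5 tab-separated columns")
            label, kind, start_s, end_s, strand = parts[:5]
            copy_index = int(parts[5]) if len(parts) > 5 and parts[5] else 1
            start1, end1 = int(start_s), int(end_s)
            if not (1 <= start1 <= n) or not (1 <= end1 <= n):
                raise ValueError(f"{table}:{lineno}: coordinates {start1}..{end1} "
                                 f"outside sequence of length {n}")
            label = canonical_label(label)
            if start1 <= end1:
                start, end = start1 - 1, end1
            else:  # wrap-around
                if not circular:
                    raise ValueError(f"{table}:{lineno}: wrap-around feature on linear sequence")
                start, end = start1 - 1, end1
            key = (label, copy_index)
            if key in keys:
                raise ValueError(f"{table}:{lineno}: duplicate feature key {key}")
            keys.add(key)
            features.append(GeneFeature(label=label, kind=kind, start=start, end=end,
                                        strand=strand, copy_index=copy_index))
    return MitoGenome(id=record.id, sequence=str(record.seq), circular=circular,
                      features=features)


def write_feature_table(genome: MitoGenome, fasta, table) -> None:
    SeqIO.write(SeqRecord(Seq(genome.sequence), id=genome.id, description=""),
                str(fasta), "fasta")
    with open(table, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write(f"{f.label}\t{f.kind}\t{f.start + 1}\t{f.end}\t{f.strand}\t{f.copy_index}\n")


def pcg_sequences(genome: MitoGenome) -> dict[str, str]:
    """Coding-sense sequences of all protein-coding genes, keyed by label."""
    out = {}
    for f in genome.features_of_kind("PCG"):
        key = f.label if f.copy_index == 1 else f"{f.label}/{f.copy_index}"
        out[key] = gene_sequence(genome, f)
    return out
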