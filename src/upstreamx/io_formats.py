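"""Readers and writers for every on-disk artifact the pipeline touches.

Formats
-------
- Promoters: FASTA, one record per gene, 1100 bp by default (positions
  -1000..+100 around the TSS, stored 5'->3' on the gene's strand; the TSS
  sits at index 1000, coordinates are 0-based half-open from sequence start).
- Motifs: TRANSFAC-style flat file (AC/ID header, ``P0`` column line,
  numbered count rows, ``//`` terminator). Count and frequency rows are both
  accepted; matrices are normalized to per-position frequencies internally.
- Signaling network: 3-column TSV edge list (source, target, target_is_tf).
- Expression: TSV count matrix (rows = genes, columns = samples) plus a
  2-column design file mapping sample -> condition.

All writers emit a ``#``-prefixed comment header recording provenance so that
stage outputs are self-describing; readers skip such lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("upstreamx")

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: pseudocount added to PWM frequencies before any log operation
DEFAULT_PSEUDOCOUNT = 0.01
#: promoter window: 1000 bp upstream + 100 bp downstream of the TSS
DEFAULT_PROMOTER_LENGTH = 1100
DEFAULT_TSS_OFFSET = 1000


class FormatError(ValueError):
    """A file violated the format contract of its reader."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Promoters (FASTA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence anchored at a transcription start site."""

    gene_id: str
    sequence: str
    tss_offset: int = DEFAULT_TSS_OFFSET

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("empty gene id")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"non-DNA character {self.sequence[pos]!r} at position {pos} "
                f"in promoter {self.gene_id!r}"
            )
        if not 0 <= self.tss_offset < len(self.sequence):
            raise FormatError(
                f"tss_offset {self.tss_offset} outside sequence of length "
                f"{len(self.sequence)} for {self.gene_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoters from FASTA.

    The gene id is the first whitespace-delimited header token; sequences are
    uppercased; the TSS offset defaults to ``length - 100`` (the promoter
    convention of 100 bp downstream context).
    """
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"empty sequence for {header!r} in {path}")
        records.append(
            PromoterRecord(header, seq, tss_offset=max(len(seq) - 100, 0))
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"empty FASTA header in {path}")
                if header in seen:
                    raise FormatError(f"duplicate id {header}")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"sequence before first header in {path}")
                chunks.append(line.strip())
        flush()
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Position weight matrices (TRANSFAC flat file)
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Position weight matrix: per-position base frequencies plus scan state.

    ``counts`` holds the raw per-position numbers from the flat file (counts
    or frequencies -- scanning is invariant to row scale). ``freqs`` are the
    pseudocount-regularized frequencies used for all log-based scores.
    """

    name: str
    counts: np.ndarray  # (L, 4) float
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    core_length: int = 5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise FormatError(f"matrix {self.name!r}: counts must be L x 4")
        if len(self.counts) < 1:
            raise FormatError(f"matrix {self.name!r}: empty")
        if (self.counts < 0).any():
            raise FormatError(f"matrix {self.name!r}: negative entry")
        row_sums = self.counts.sum(axis=1)
        if (row_sums <= 0).any():
            bad = int(np.argmax(row_sums <= 0))
            raise FormatError(
                f"matrix {self.name!r}: row {bad + 1} sums to zero"
            )
        if self.pseudocount < 0:
            raise FormatError(f"matrix {self.name!r}: negative pseudocount")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def freqs(self) -> np.ndarray:
        """Pseudocount-regularized frequencies; each row sums to 1."""
        f = self.counts / self.counts.sum(axis=1, keepdims=True)
        f = f + self.pseudocount
        return f / f.sum(axis=1, keepdims=True)


def read_transfac_matrices(path: str | Path,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT,
                           ) -> list[Pwm]:
    """Parse a TRANSFAC-style matrix flat file.

    Each record: optional ``AC``/``ID`` lines (ID preferred as the name),
    a ``P0`` (or ``PO``) column header, numbered rows ``01 a c g t
    [consensus]`` starting at 01 and consecutive, terminated by ``//``.
    """
    pwms: list[Pwm] = []
    name: str | None = None
    acc: str | None = None
    rows: list[list[float]] = []
    in_record = False
    last_lineno = 0

    def close(lineno: int) -> None:
        nonlocal name, acc, rows, in_record
        if not in_record:
            return
        if not rows:
            raise FormatError(f"{path}:{lineno}: matrix record with no rows")
        label = name or acc
        if not label:
            raise FormatError(f"{path}:{lineno}: matrix record without ID/AC")
        pwms.append(Pwm(label, np.array(rows), pseudocount=pseudocount))
        name = acc = None
        rows = []
        in_record = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            last_lineno = lineno
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("XX") or line.startswith("#"):
                continue
            tag = line[:2]
            if tag == "//":
                close(lineno)
                continue
            in_record = True
            if tag == "AC":
                acc = line[2:].strip()
            elif tag == "ID":
                name = line[2:].strip()
            elif tag in ("P0", "PO"):
                continue
            elif tag.isdigit():
                expected = len(rows) + 1
                if int(tag) != expected:
                    raise FormatError(
                        f"{path}:{lineno}: row number {tag} out of order "
                        f"(expected {expected:02d})"
                    )
                fields = line[2:].split()
                numeric = fields[:4]
                if len(numeric) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: matrix row needs 4 numeric fields, "
                        f"got {len(numeric)}"
                    )
                try:
                    rows.append([float(x) for x in numeric])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            # other tags (BF, DE, CC ...) are metadata; ignored
    if in_record:
        raise FormatError(f"{path}:{last_lineno}: missing '//' terminator at EOF")
    return pwms


def write_transfac_matrices(pwms: Iterable[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.name}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.counts, 1):
                vals = "  ".join(f"{v:g}" for v in row)
                fh.write(f"{i:02d}  {vals}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Signaling network (TSV edge list)
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


@dataclass
class SignalingNetwork:
    """Directed signaling graph; an edge (u, v) means u acts upstream of v."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    tf_nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def add_edge(self, source: str, target: str) -> bool:
        """Add an edge, dropping self-loops (returns False when dropped)."""
        if source == target:
            logger.warning("dropping self-loop %s -> %s", source, target)
            self.graph.add_node(source)
            return False
        self.graph.add_edge(source, target)
        return True

    def flag_tf(self, node: str) -> None:
        self.graph.add_node(node)
        self.tf_nodes.add(node)

    def validate(self) -> None:
        extra = self.tf_nodes - self.nodes
        if extra:
            raise FormatError(f"tf_nodes not in graph: {sorted(extra)[:5]}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise FormatError(f"self-loops present after load: {loops[:5]}")


def read_network(path: str | Path) -> SignalingNetwork:
    net = SignalingNetwork()
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if fields[:3] != ["source", "target", "target_is_tf"]:
                    raise FormatError(
                        f"{path}:{lineno}: expected header "
                        "'source\\ttarget\\ttarget_is_tf'"
                    )
                continue
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            source, target, flag = fields
            if flag in _TRUE:
                is_tf = True
            elif flag in _FALSE:
                is_tf = False
            else:
                raise FormatError(
                    f"{path}:{lineno}: bad target_is_tf value {flag!r} "
                    "(expected 0/1/true/false)"
                )
            net.add_edge(source, target)
            if is_tf:
                net.flag_tf(target)
    net.validate()
    return net


def write_network(net: SignalingNetwork, path: str | Path,
                  comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("source\ttarget\ttarget_is_tf\n")
        for source, target in sorted(net.graph.edges):
            flag = "1" if target in net.tf_nodes else "0"
            fh.write(f"{source}\t{target}\t{flag}\n")


# ---------------------------------------------------------------------------
# Count matrix (TSV + design sidecar)
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample integer read counts with a sample -> condition design."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids, int
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise FormatError(f"sample {missing[0]!r} missing from design")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative count")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == condition]


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for sample in df.columns:
        col = df[sample]
        as_float = pd.to_numeric(col, errors="coerce")
        if as_float.isna().any():
            gene = col.index[as_float.isna()][0]
            raise FormatError(
                f"non-numeric count at gene {gene!r}, sample {sample!r}"
            )
        if not (as_float == as_float.round()).all():
            gene = col.index[as_float != as_float.round()][0]
            raise FormatError(
                f"non-integer count {col[gene]!r} at gene {gene!r}, "
                f"sample {sample!r}"
            )
    df = df.astype(np.int64)
    design = pd.read_csv(design_path, sep="\t", comment="#",
                         dtype=str, header=0)
    if list(design.columns[:2]) != ["sample", "condition"]:
        raise FormatError(
            f"{design_path}: expected header 'sample\\tcondition'"
        )
    condition_of = dict(zip(design["sample"], design["condition"]))
    return CountMatrix(df, condition_of)


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 design_path: str | Path) -> None:
    with open(counts_path, "w") as fh:
        cm.counts.to_csv(fh, sep="\t", index_label="gene_id")
    with open(design_path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample in cm.sample_ids:
            fh.write(f"{sample}\t{cm.condition_of[sample]}\n")


# ---------------------------------------------------------------------------
# Generic TSV table output with provenance header
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, *,
                params: Mapping[str, object] | None = None,
                seed: int | None = None,
                index: bool = False) -> None:
    """Write a TSV with a ``#`` comment header recording tool version,
    seed and parameters."""
    from upstreamx import __version__

    with open(path, "w") as fh:
        fh.write(f"# upstreamx {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
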