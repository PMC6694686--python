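"""PAM-site scanning over reference sequences.

Locates every occurrence of a Cas enzyme's PAM motif on both strands of a
sequence. Coordinates are 0-based half-open on the forward reference strand
throughout (and in BED output); the strand records the orientation in which
the motif reads canonically. Overlapping and nested occurrences are all
reported — each anchors distinct guides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cas import IUPAC, CasEnzyme, CasRegistry, reverse_complement_motif

__all__ = ["PamSite", "scan_sequence", "scan_genome"]


@dataclass(frozen=True, order=True)
class PamSite:
    """A located PAM occurrence. ``end - start == len(pam_motif)``."""

    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cas_name: str


def _match_offsets(seq_bytes: np.ndarray, motif: str) -> np.ndarray:
    """Offsets i where seq[i:i+len(motif)] matches the IUPAC motif.

    Vectorized per motif position; windows containing non-ACGT bytes
    (assembly N etc.) never match because allowed sets contain only ACGT.
    """
    L = len(motif)
    n = seq_bytes.size
    if n < L:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(n - L + 1, dtype=bool)
    for j, code in enumerate(motif):
        allowed = np.frombuffer("".join(sorted(IUPAC[code])).encode(), dtype=np.uint8)
        mask &= np.isin(seq_bytes[j : j + n - L + 1], allowed)
    return np.nonzero(mask)[0]


def scan_sequence(seq: str, cas: CasEnzyme, contig: str = "seq") -> list[PamSite]:
    """All PAM occurrences of ``cas`` on both strands of ``seq``.

    Soft-masked (lowercase) bases are uppercased first. Returns sites sorted
    by (start, strand); an empty sequence yields an empty list.
    """
    seq_bytes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    L = cas.pam_length
    sites = [
        PamSite(contig, int(i), int(i) + L, "+", cas.name)
        for i in _match_offsets(seq_bytes, cas.pam_motif)
    ]
    sites += [
        PamSite(contig, int(i), int(i) + L, "-", cas.name)
        for i in _match_offsets(seq_bytes, reverse_complement_motif(cas.pam_motif))
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _read_fasta_sequences(fasta_path: str | Path) -> list[tuple[str, str]]:
    """Plain FASTA reader returning (name, sequence) in file order.

    Raises OSError for unreadable files or duplicate contig names.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise OSError(f"FASTA not found: {path}")
    names: list[str] = []
    chunks: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in chunks:
                    raise OSError(f"duplicate contig {current!r} in {path}")
                names.append(current)
                chunks[current] = []
            elif current is None:
                raise OSError(f"{path}: sequence data before any FASTA header")
            else:
                chunks[current].append(line)
    return [(name, "".join(chunks[name])) for name in names]


def scan_genome(
    fasta_path: str | Path,
    registry: CasRegistry,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Scan every contig of a FASTA for every registry enzyme.

    Writes one 6-column BED per enzyme (``<name>.pams.bed``; name column is
    the Cas name, score 0) under ``out_dir`` and returns a summary count
    table with columns contig, cas_name, n_sites.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences = _read_fasta_sequences(fasta_path)
    rows = []
    for cas in registry.enzymes:
        bed_path = out_dir / f"{cas.name}.pams.bed"
        with open(bed_path, "w") as bed:
            for contig, seq in sequences:
                sites = scan_sequence(seq, cas, contig=contig)
                for s in sites:
                    bed.write(
                        f"{s.contig}\t{s.start}\t{s.end}\t{s.cas_name}\t0\t{s.strand}\n"
                    )
                rows.append(
                    {"contig": contig, "cas_name": cas.name, "n_sites": len(sites)}
                )
    return pd.DataFrame(rows, columns=["contig", "cas_name", "n_sites"])
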