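"""Plain-text readers and writers for alignments and site labels."""

from __future__ import annotations

import numpy as np

from .gtr import BASES
from .simulate import LabeledAlignment

__all__ = ["read_fasta", "read_labels_tsv", "read_alignment"]

_INDEX = {b: i for i, b in enumerate(BASES)}


def read_fasta(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a nucleotide FASTA file into (taxa, state matrix).

    Sequences are reordered to alphabetical taxon order; only A/C/G/T
    are accepted (the models have no ambiguity or gap states).
    """
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate sequence name {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("sequence data before any header")
                seqs[name].append(line.upper())
    if not seqs:
        raise ValueError("empty FASTA file")
    taxa = tuple(sorted(seqs))
    rows = []
    for t in taxa:
        s = "".join(seqs[t])
        try:
            rows.append([_INDEX[c] for c in s])
        except KeyError as e:
            raise ValueError(f"unsupported character {e} in {t!r}") from e
    mat = np.asarray(rows, dtype=np.int8)
    if len({r.size for r in mat}) > 1:
        raise ValueError("sequences have unequal lengths")
    return taxa, mat


def read_labels_tsv(path, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Read the per-site (fitted_block, true_origin) sidecar table."""
    fitted = np.zeros(n_sites, dtype=np.int8)
    origin = np.zeros(n_sites, dtype=np.int8)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            i = int(parts[cols["site"]]) - 1
            fitted[i] = int(parts[cols["fitted_block"]])
            origin[i] = int(parts[cols.get("true_origin", cols["fitted_block"])])
    if np.any(fitted == 0):
        raise ValueError("labels missing for some sites")
    return fitted, origin


def read_alignment(fasta_path, labels_path=None) -> LabeledAlignment:
    """Assemble a :class:`LabeledAlignment` from FASTA plus label TSV.

    Without a label file the first half of the sites is block 1 and the
    second half block 2 (the study's fixed partitioning scheme).
    """
    taxa, mat = read_fasta(fasta_path)
    n = mat.shape[1]
    if labels_path is None:
        fitted = np.where(np.arange(n) < n // 2, 1, 2).astype(np.int8)
        origin = fitted.copy()
    else:
        fitted, origin = read_labels_tsv(labels_path, n)
    return LabeledAlignment(taxa, mat, fitted, origin)
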