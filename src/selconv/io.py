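"""Input containers and readers: codon alignments, domain partitions,
branch tags and per-column confidence tracks.

Coordinates are 0-based half-open throughout, and codon coordinates equal
amino-acid coordinates.  TGA is tolerated only at the declared catalytic
column, where it encodes selenocysteine (protein symbol ``U``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import PhyloTree
from . import codon as _codon


class InputError(ValueError):
    pass


@dataclass
class DomainPartition:
    """Ordered, non-overlapping named intervals in amino-acid coordinates."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self):
        names = [n for n, _, _ in self.intervals]
        if len(set(names)) != len(names):
            raise InputError("domain names must be unique")
        prev_end = 0
        for name, start, end in self.intervals:
            if not (0 <= start < end):
                raise InputError(f"bad interval for {name!r}: [{start}, {end})")
            if start < prev_end:
                raise InputError(f"domains overlap or are unsorted at {name!r}")
            prev_end = end

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.intervals]

    @property
    def total_end(self) -> int:
        return self.intervals[-1][2]

    def get(self, name: str) -> tuple[int, int]:
        for n, s, e in self.intervals:
            if n == name:
                return s, e
        raise InputError(f"unknown region {name!r}; have {self.names}")

    def domain_of_site(self, site: int) -> str | None:
        for n, s, e in self.intervals:
            if s <= site < e:
                return n
        return None

    def lengths(self) -> dict[str, int]:
        return {n: e - s for n, s, e in self.intervals}

    @classmethod
    def read_tsv(cls, path) -> "DomainPartition":
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = {c.lower(): c for c in df.columns}
        need = {"name", "start", "end"}
        if not need <= set(cols):
            raise InputError(f"domain table must have columns {sorted(need)}")
        ivals = [(str(r[cols["name"]]), int(r[cols["start"]]), int(r[cols["end"]]))
                 for _, r in df.iterrows()]
        return cls(ivals)

    def write_tsv(self, path):
        pd.DataFrame(self.intervals, columns=["name", "start", "end"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ColumnConfidence:
    """Per amino-acid/codon column alignment confidence in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("confidence track must be one-dimensional")
        if np.any((self.values < 0) | (self.values > 1)) or not np.all(
            np.isfinite(self.values)
        ):
            raise InputError("confidence values must lie in [0, 1]")

    @classmethod
    def read_tsv(cls, path) -> "ColumnConfidence":
        df = pd.read_csv(path, sep="\t", comment="#")
        col = "confidence" if "confidence" in df.columns else df.columns[-1]
        return cls(df[col].to_numpy())

    def write_tsv(self, path):
        pd.DataFrame({
            "column": np.arange(len(self.values)),
            "confidence": self.values,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class CodonAlignment:
    """In-frame codon alignment.

    ``codons`` is an (n_taxa, n_codons) array of 3-mer strings (gaps as
    ``---``).  ``catalytic_site`` is the codon coordinate of the catalytic
    residue (or None); ``column_map`` maps current columns back to the
    coordinates of the originally loaded alignment.
    """

    taxa: list[str]
    codons: np.ndarray
    catalytic_site: int | None = None
    column_map: np.ndarray | None = None

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise InputError("codon matrix shape must be (n_taxa, n_codons)")
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxon names")
        if self.column_map is None:
            self.column_map = np.arange(self.codons.shape[1])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @property
    def nuc_length(self) -> int:
        return 3 * self.n_codons

    def sequence(self, taxon: str) -> str:
        return "".join(self.codons[self.taxa.index(taxon)])

    # ------------------------------------------------------------------
    @classmethod
    def from_sequences(cls, taxa, nuc_seqs, catalytic_site=None) -> "CodonAlignment":
        rows = []
        length = None
        for name, seq in zip(taxa, nuc_seqs):
            seq = str(seq).upper().replace("U", "T")
            if len(seq) % 3 != 0:
                raise InputError(
                    f"sequence for {name!r} has length {len(seq)}, not a "
                    "multiple of 3"
                )
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise InputError(f"sequence length mismatch at {name!r}")
            rows.append([seq[i:i + 3] for i in range(0, len(seq), 3)])
        aln = cls(list(taxa), np.array(rows, dtype="<U3"), catalytic_site)
        aln.check_stops()
        return aln

    @classmethod
    def read_fasta(cls, path, catalytic_site=None) -> "CodonAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise InputError(f"no sequences in {path}")
        return cls.from_sequences([r.id for r in recs], [r.seq for r in recs],
                                  catalytic_site)

    def write_fasta(self, path):
        recs = [SeqRecord(Seq(self.sequence(t)), id=t, description="")
                for t in self.taxa]
        SeqIO.write(recs, str(path), "fasta")

    # ------------------------------------------------------------------
    def check_stops(self):
        """No internal stop codons; TGA allowed only at the catalytic site."""
        stops = _codon.GENETIC_CODE.stop_codons
        for i, taxon in enumerate(self.taxa):
            for j in range(self.n_codons):
                c = self.codons[i, j]
                if c in stops and j != self.catalytic_site:
                    raise InputError(
                        f"stop codon {c} in {taxon!r} at codon column {j} "
                        "(outside the catalytic site)"
                    )
                if c in ("TAA", "TAG") and j == self.catalytic_site:
                    raise InputError(
                        f"non-Sec stop codon {c} at the catalytic site in {taxon!r}"
                    )

    def protein(self, sec_as: str = "U") -> dict[str, str]:
        """Translate to protein; catalytic TGA becomes ``sec_as``."""
        out = {}
        for i, taxon in enumerate(self.taxa):
            aa = []
            for j in range(self.n_codons):
                c = self.codons[i, j]
                if c == "---" or "-" in c:
                    aa.append("-")
                elif c == "TGA" and j == self.catalytic_site:
                    aa.append(sec_as)
                else:
                    aa.append(_codon.GENETIC_CODE.translate(c))
            out[taxon] = "".join(aa)
        return out

    def drop_columns(self, cols) -> "CodonAlignment":
        keep = np.ones(self.n_codons, dtype=bool)
        keep[list(cols)] = False
        return self.keep_columns(np.nonzero(keep)[0])

    def keep_columns(self, cols) -> "CodonAlignment":
        cols = np.asarray(cols, dtype=int)
        cat = None
        if self.catalytic_site is not None:
            hit = np.nonzero(cols == self.catalytic_site)[0]
            cat = int(hit[0]) if len(hit) else None
        return CodonAlignment(
            list(self.taxa), self.codons[:, cols], cat, self.column_map[cols]
        )


# ----------------------------------------------------------------------
def read_branch_tags(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if not {"branch", "tag"} <= set(cols):
        raise InputError("tag table must have columns 'branch' and 'tag'")
    return {str(r[cols["branch"]]): str(r[cols["tag"]]).upper()
            for _, r in df.iterrows()}


def write_branch_tags(tree: PhyloTree, path):
    rows = [{"branch": tree.names[b] or f"node{b}", "tag": tree.tags[b]}
            for b in tree.branches]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_inputs(alignment_file, tree_file, tags, domains,
                catalytic_site: int | None = None):
    """Load and cross-validate the full input bundle.

    ``tags`` and ``domains`` may be paths to TSV files or already-built
    dict / DomainPartition objects.  Returns (CodonAlignment, PhyloTree,
    DomainPartition).
    """
    aln = CodonAlignment.read_fasta(alignment_file, catalytic_site)
    tree = PhyloTree.from_newick(str(tree_file), is_path=True)
    tag_map = tags if isinstance(tags, dict) else read_branch_tags(tags)
    tree.set_tags(tag_map)
    dom = domains if isinstance(domains, DomainPartition) else DomainPartition.read_tsv(domains)

    aln_taxa, tree_taxa = set(aln.taxa), set(tree.leaf_names)
    if aln_taxa != tree_taxa:
        miss_a = sorted(tree_taxa - aln_taxa)
        miss_t = sorted(aln_taxa - tree_taxa)
        raise InputError(
            f"taxon mismatch: missing from alignment {miss_a}, "
            f"missing from tree {miss_t}"
        )
    if dom.total_end > aln.n_codons:
        raise InputError(
            f"domain partition extends to {dom.total_end} but alignment has "
            f"{aln.n_codons} codons"
        )
    return aln, tree, dom


# ----------------------------------------------------------------------
def apply_column_mask(aln: CodonAlignment, conf: ColumnConfidence,
                      threshold: float = 0.95,
                      domains: DomainPartition | None = None):
    """Drop codon columns whose confidence falls below ``threshold``.

    Returns (masked alignment, remapped domains or None).  Domain
    intervals are remapped onto the retained-column coordinate system;
    the old->new mapping is kept on the alignment's ``column_map``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InputError("threshold must be in [0, 1]")
    if len(conf.values) != aln.n_codons:
        raise InputError(
            f"confidence track has {len(conf.values)} columns, alignment has "
            f"{aln.n_codons}"
        )
    keep = np.nonzero(conf.values >= threshold)[0]
    if len(keep) == 0:
        warnings.warn("all columns masked; alignment is empty")
    masked = aln.keep_columns(keep)
    new_dom = None
    if domains is not None:
        ivals = []
        for name, s, e in domains.intervals:
            n_kept = int(np.sum((keep >= s) & (keep < e)))
            start = int(np.sum(keep < s))
            if n_kept > 0:
                ivals.append((name, start, start + n_kept))
        new_dom = DomainPartition(ivals) if ivals else None
    return masked, new_dom


def extract_region(aln: CodonAlignment, domains: DomainPartition | None,
                   region: str = "full",
                   exclude_catalytic: bool = False) -> CodonAlignment:
    """Sub-alignment for a named domain (or "full"), optionally removing
    the catalytic column when it falls inside the region."""
    if region == "full":
        s, e = 0, aln.n_codons
    else:
        if domains is None:
            raise InputError("no domain partition supplied")
        s, e = domains.get(region)
    cols = np.arange(s, e)
    if exclude_catalytic and aln.catalytic_site is not None:
        cols = cols[cols != aln.catalytic_site]
    return aln.keep_columns(cols)
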