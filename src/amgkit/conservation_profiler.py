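"""Active-site conservation profiling and clade-group assignment for chitosanases.

GH75 chitosanases share four conserved acidic active-site positions
(canonically D-D-D-E; in the viral enzyme V-Csn these are D34, D36, D148 and
E157).  Given a multiple sequence alignment of family members and a
phylogenetic tree, this module

* trims the alignment to the region spanned by the key columns plus
  well-aligned flanks (columns where fewer than 10% of sequences are gapped),
* extracts the per-sequence residues at the four key columns,
* tabulates per-column residue frequencies, and
* assigns clade-aware group labels that combine tree clade membership with
  the site-1 residue variant (D / C / N).

Alignment construction (MAFFT) and tree inference (RAxML) are upstream of
this module; their outputs are inputs here.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = {"-", "."}
DEFAULT_GAP_THRESHOLD = 0.10  # strict "<10% of the sequences had a gap"


class GroupLabel(str, enum.Enum):
    """Clade + key-residue variant groups of viral chitosanases."""

    GROUP1_1 = "Group1.1"   # Clade 1, cysteine at site 1
    GROUP1_2 = "Group1.2"   # Clade 1, canonical aspartate
    GROUP2 = "Group2"       # Clade 2 (canonical residues)
    GROUP3_1 = "Group3.1"   # Clade 3, asparagine at site 1
    GROUP3_2 = "Group3.2"   # Clade 3, canonical aspartate
    OTHER = "other"


@dataclass
class Alignment:
    """A protein multiple sequence alignment (ids + equal-length rows)."""

    ids: list
    seqs: list

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.seqs)

    def gap_fraction(self, i: int) -> float:
        col = self.column(i)
        return sum(c in GAP_CHARS for c in col) / len(col)

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        msa = AlignIO.read(source, "fasta")
        return cls([r.id for r in msa], [str(r.seq) for r in msa])

    def to_fasta(self, path_or_handle) -> None:
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(self.ids, self.seqs))
        AlignIO.write(msa, path_or_handle, "fasta")

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()


@dataclass
class KeySiteProfile:
    """Residues at the four key active-site columns, per sequence and pooled.

    ``frequencies`` maps column index -> residue -> percentage over sequences
    with a non-gap residue at that column; the gap fraction per column is kept
    separately in ``gap_percent``.
    """

    key_columns: list
    per_sequence: dict
    frequencies: dict = field(default_factory=dict)
    gap_percent: dict = field(default_factory=dict)

    def site_residue(self, seq_id: str, site: int) -> str:
        return self.per_sequence[seq_id][site]


def _check_key_columns(aln: Alignment, key_columns) -> list:
    cols = list(key_columns)
    if sorted(set(cols)) != cols:
        raise ValueError("key columns must be distinct and increasing")
    if cols and (cols[0] < 0 or cols[-1] >= aln.n_columns):
        raise ValueError(f"key columns {cols} outside alignment "
                         f"of width {aln.n_columns}")
    return cols


def filter_alignment_columns(aln: Alignment, key_columns,
                             gap_threshold: float = DEFAULT_GAP_THRESHOLD):
    """Trim the alignment to the key-column span plus well-aligned flanks.

    Columns between the first and last key column (inclusive) are always
    retained.  Flanking columns outside that span are retained only when their
    gap fraction is strictly below ``gap_threshold``.  Column order is
    preserved.  Returns ``(trimmed, retained_indices)`` where
    ``retained_indices`` maps trimmed columns back to the input alignment.
    """
    cols = _check_key_columns(aln, key_columns)
    first, last = cols[0], cols[-1]
    retained = [i for i in range(aln.n_columns)
                if first <= i <= last or aln.gap_fraction(i) < gap_threshold]
    trimmed = Alignment(list(aln.ids),
                        ["".join(s[i] for i in retained) for s in aln.seqs])
    return trimmed, retained


def extract_key_sites(aln: Alignment, key_columns) -> KeySiteProfile:
    """Per-sequence residue tuples at the key columns plus frequency tables."""
    cols = _check_key_columns(aln, key_columns)
    per_seq = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        per_seq[sid] = tuple("-" if seq[c] in GAP_CHARS else seq[c].upper()
                             for c in cols)
    profile = KeySiteProfile(cols, per_seq)
    profile.frequencies, profile.gap_percent = _frequency_tables(profile, aln.ids)
    return profile


def _frequency_tables(profile: KeySiteProfile, subset):
    freqs, gaps = {}, {}
    for site, col in enumerate(profile.key_columns):
        residues = [profile.per_sequence[sid][site] for sid in subset]
        non_gap = [r for r in residues if r != "-"]
        counts = {}
        for r in non_gap:
            counts[r] = counts.get(r, 0) + 1
        freqs[col] = {r: 100.0 * c / len(non_gap)
                      for r, c in sorted(counts.items())} if non_gap else {}
        gaps[col] = 100.0 * (len(residues) - len(non_gap)) / len(residues)
    return freqs, gaps


def residue_frequencies(profile: KeySiteProfile, subset=None) -> pd.DataFrame:
    """Relative residue frequencies (%) at each key column.

    The denominator is the number of subset sequences with a non-gap residue
    at that column; gap percentages are reported in separate rows labelled
    ``'-'`` against the full subset size, so either denominator convention can
    be recomputed from the output.
    """
    subset = list(subset) if subset is not None else list(profile.per_sequence)
    if not subset:
        raise ValueError("empty sequence subset")
    missing = set(subset) - set(profile.per_sequence)
    if missing:
        raise KeyError(f"ids not in profile: {sorted(missing)}")
    freqs, gaps = _frequency_tables(profile, subset)
    rows = []
    for site, col in enumerate(profile.key_columns):
        for res, pct in freqs[col].items():
            rows.append({"site": site + 1, "column": col,
                         "residue": res, "percent": round(pct, 2)})
        if gaps[col]:
            rows.append({"site": site + 1, "column": col,
                         "residue": "-", "percent": round(gaps[col], 2)})
    return pd.DataFrame(rows, columns=["site", "column", "residue", "percent"])


def assign_group(site_tuple, clade: str) -> GroupLabel:
    """Combine clade membership and the site-1 variant into a group label.

    Clade 1 sequences carry either the cysteine substitution (Group 1.1) or
    the canonical aspartate (Group 1.2); Clade 2 is uniform (Group 2); Clade 3
    splits into asparagine-substituted (Group 3.1) and canonical (Group 3.2).
    Any other clade, or an unexpected site-1 residue, maps to ``other``.
    """
    site1 = site_tuple[0].upper() if site_tuple and site_tuple[0] else "-"
    clade = (clade or "").strip()
    if clade == "Clade1":
        if site1 == "C":
            return GroupLabel.GROUP1_1
        if site1 == "D":
            return GroupLabel.GROUP1_2
    elif clade == "Clade2":
        return GroupLabel.GROUP2
    elif clade == "Clade3":
        if site1 == "N":
            return GroupLabel.GROUP3_1
        if site1 == "D":
            return GroupLabel.GROUP3_2
    return GroupLabel.OTHER


def read_clade_map(path) -> dict:
    """Read a two-column TSV (sequence id, clade) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def annotate_tree(tree, profile: KeySiteProfile, clades: dict,
                  habitats: dict | None = None):
    """Attach per-leaf metadata (clade, group, key residues) to a tree.

    ``tree`` may be a Newick string/path or a :class:`dendropy.Tree`.  The
    topology is untouched; the return value is ``(tree, table)`` where
    ``table`` has one row per leaf with its clade, group label, the four key
    residues (ring order: site 1 innermost) and optional habitat.  Leaves
    absent from the profile are flagged and given gap residues.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if "(" not in text:  # a path rather than newick text
            with open(text) as fh:
                text = fh.read()
        try:
            t = dendropy.Tree.get(data=text, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf names in tree: {exc}") from exc
    names = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in tree")
    habitats = habitats or {}
    rows = []
    for name in names:
        in_profile = name in profile.per_sequence
        residues = (profile.per_sequence[name] if in_profile
                    else ("-",) * len(profile.key_columns))
        clade = clades.get(name, "")
        rows.append({
            "leaf": name,
            "clade": clade,
            "group": assign_group(residues, clade).value,
            **{f"site{i + 1}": r for i, r in enumerate(residues)},
            "habitat": habitats.get(name, ""),
            "in_profile": in_profile,
        })
    return t, pd.DataFrame(rows)
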