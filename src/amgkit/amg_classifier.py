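"""Confidence classification of putative viral auxiliary metabolic genes (AMGs).

Viral contigs recovered from metagenomes frequently carry genes that look
metabolic rather than viral (e.g. GH75 chitosanases).  Whether such a gene is
really virus-encoded, rather than contaminating host sequence, is judged from
its genomic context: the annotation classes of the genes upstream and
downstream of the candidate.  This module implements

* the multi-database corroboration screen for candidate proteins,
* the lysozyme-HMM exclusion filter (chitosanase HMMs cross-react with
  lysozymes),
* the five-category genomic-context confidence classification,
* retention of high-confidence contigs (categories 0-2), and
* the two-of-three consensus host call from external host-prediction tools.

HMM/BLAST searching itself is out of scope; hit tables produced by those tools
are inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

# Annotation class labels carried by genes on a viral contig.
HALLMARK = "hallmark"              # structural proteins, terminases, integrases
VIRAL_SPECIFIC = "viral_specific"  # viral but not hallmark
MICROBIAL = "microbial"
UNANNOTATED = "unannotated"
AMG_CANDIDATE = "amg_candidate"

GENE_LABELS = {HALLMARK, VIRAL_SPECIFIC, MICROBIAL, UNANNOTATED, AMG_CANDIDATE}

# Databases that may corroborate a pfam chitosanase assignment.  The lysozyme
# profile is a *negative* screen and never counts as corroboration.
MANDATORY_DATABASE = "pfam_chitosanase"
CORROBORATING_DATABASES = {"eggnog", "cazy", "foam", "ncbi_blastp"}
LYSOZYME_DATABASE = "lysozyme_hmm"
KNOWN_DATABASES = {MANDATORY_DATABASE, LYSOZYME_DATABASE} | CORROBORATING_DATABASES

HOST_TOOLS = ("WIsH", "VirHostMatcher", "PHP")

#: Conventional order of ranks in a semicolon-separated lineage string.
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

DEFAULT_LYSOZYME_EVALUE = 1e-5


class AmgCategory(enum.IntEnum):
    """Genomic-context confidence class; smaller numbers mean higher confidence."""

    HALLMARK_BOTH_SIDES = 0
    VIRAL_BOTH_HALLMARK_ONE = 1
    VIRAL_BOTH_SIDES = 2
    VIRAL_ONE_SIDE = 3
    ON_EDGE = 4


@dataclass(frozen=True)
class GeneRecord:
    """One gene on a viral contig.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates; ``labels``
    is a set drawn from :data:`GENE_LABELS`.
    """

    contig_id: str
    index: int
    start: int
    end: int
    strand: str
    labels: frozenset = frozenset()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.contig_id}:{self.index}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        unknown = set(self.labels) - GENE_LABELS
        if unknown:
            raise ValueError(f"unknown gene labels {sorted(unknown)}")


@dataclass
class AnnotatedContig:
    """A viral contig with its ordered gene records."""

    contig_id: str
    length: int
    genes: list = field(default_factory=list)
    circular: bool = False

    def __post_init__(self):
        prev_start = 0
        for g in self.genes:
            if g.end > self.length or g.start < 1:
                raise ValueError(
                    f"gene {g.index} outside contig bounds [1, {self.length}]")
            if g.start < prev_start:
                raise ValueError("gene records must be ordered by start")
            prev_start = g.start

    def __len__(self):
        return len(self.genes)

    def amg_indices(self) -> list:
        return [g.index for g in self.genes if AMG_CANDIDATE in g.labels]


@dataclass
class HostCall:
    """Per-tool host taxonomy plus the two-of-three consensus."""

    contig_id: str
    per_tool: dict
    consensus: str
    agreement_level: int


# ---------------------------------------------------------------------------
# Candidate screening
# ---------------------------------------------------------------------------

def _validate_hit_table(hits: pd.DataFrame) -> pd.DataFrame:
    required = {"protein_id", "database"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    unknown = set(hits["database"]) - KNOWN_DATABASES
    if unknown:
        raise ValueError(f"unknown database tags {sorted(unknown)}")
    if "evalue" in hits.columns and (hits["evalue"].dropna() < 0).any():
        raise ValueError("e-values must be non-negative")
    return hits


def screen_candidates(hits: pd.DataFrame, required_databases=None,
                      min_databases: int = 1) -> set:
    """Proteins with a pfam chitosanase hit corroborated by other databases.

    A protein is retained iff it has a ``pfam_chitosanase`` hit and hits in at
    least ``min_databases`` distinct corroborating sources (EggNOG, CAZy,
    FOAM, NCBI blastp by default).
    """
    _validate_hit_table(hits)
    if required_databases is None:
        required_databases = CORROBORATING_DATABASES
    else:
        unknown = set(required_databases) - CORROBORATING_DATABASES
        if unknown:
            raise ValueError(f"unknown corroborating databases {sorted(unknown)}")
        required_databases = set(required_databases)
    retained = set()
    for pid, sub in hits.groupby("protein_id"):
        dbs = set(sub["database"])
        if MANDATORY_DATABASE not in dbs:
            continue
        if len(dbs & required_databases) >= min_databases:
            retained.add(pid)
    return retained


def exclude_lysozymes(candidates: set, hits: pd.DataFrame,
                      evalue_threshold: float = DEFAULT_LYSOZYME_EVALUE) -> set:
    """Drop candidates with a significant lysozyme-profile hit.

    Chitosanase HMMs pick up phage lysozymes; any candidate with a
    ``lysozyme_hmm`` hit at e-value <= *evalue_threshold* is removed.
    """
    _validate_hit_table(hits)
    lys = hits[hits["database"] == LYSOZYME_DATABASE]
    if "evalue" not in lys.columns and len(lys):
        raise ValueError("lysozyme rows must carry e-values")
    flagged = set(lys.loc[lys["evalue"] <= evalue_threshold, "protein_id"])
    return set(candidates) - flagged


# ---------------------------------------------------------------------------
# Genomic-context categories
# ---------------------------------------------------------------------------

def _neighbourhoods(contig: AnnotatedContig, amg_index: int, window=None):
    """Upstream/downstream gene lists around position ``amg_index``.

    Linear contigs: everything with a smaller index is upstream, larger is
    downstream.  Circular contigs: neighbours wrap around and each side is
    truncated at the antipodal gene (which, when the gene count is even,
    belongs to neither side).  ``window`` optionally caps the number of genes
    considered per side.
    """
    n = len(contig.genes)
    if not 0 <= amg_index < n:
        raise IndexError(f"amg_index {amg_index} out of range for {n} genes")
    if not contig.circular:
        upstream = contig.genes[:amg_index]
        downstream = contig.genes[amg_index + 1:]
        # nearest-first ordering so a window keeps the closest genes
        upstream = upstream[::-1]
    else:
        upstream, downstream = [], []
        for g in contig.genes:
            if g.index == amg_index:
                continue
            back = (amg_index - g.index) % n
            fwd = (g.index - amg_index) % n
            if back < fwd:
                upstream.append((back, g))
            elif fwd < back:
                downstream.append((fwd, g))
            # back == fwd: antipodal, excluded from both
        upstream = [g for _, g in sorted(upstream, key=lambda t: t[0])]
        downstream = [g for _, g in sorted(downstream, key=lambda t: t[0])]
    if window is not None:
        upstream = upstream[:window]
        downstream = downstream[:window]
    return upstream, downstream


def categorize_amg(contig: AnnotatedContig, amg_index: int,
                   window=None) -> AmgCategory:
    """Assign the five-category genomic-context confidence class.

    Category 0: viral hallmark genes both upstream and downstream.
    Category 1: viral-specific genes on both sides plus a hallmark gene on at
    least one side.  Category 2: viral-specific genes on both sides, no
    hallmark.  Category 3: viral-specific genes on one side only.  Category 4:
    the candidate sits on an edge of a linear contig.

    The edge test runs first; categories 0-3 are then evaluated in numeric
    order (decreasing confidence), which makes the definitions' negative
    clauses redundant.  Hallmark genes count as viral-specific for the
    both-sides tests.  A context with no viral gene on either side falls
    through to category 3, the weakest non-edge class.
    """
    upstream, downstream = _neighbourhoods(contig, amg_index, window)
    if not contig.circular and (not upstream or not downstream):
        return AmgCategory.ON_EDGE

    def has(genes, label):
        return any(label in g.labels for g in genes)

    hall_up = has(upstream, HALLMARK)
    hall_down = has(downstream, HALLMARK)
    # hallmark genes are viral by definition
    viral_up = hall_up or has(upstream, VIRAL_SPECIFIC)
    viral_down = hall_down or has(downstream, VIRAL_SPECIFIC)

    if hall_up and hall_down:
        return AmgCategory.HALLMARK_BOTH_SIDES
    if viral_up and viral_down and (hall_up or hall_down):
        return AmgCategory.VIRAL_BOTH_HALLMARK_ONE
    if viral_up and viral_down:
        return AmgCategory.VIRAL_BOTH_SIDES
    return AmgCategory.VIRAL_ONE_SIDE


def retain_high_confidence(categorized) -> list:
    """Keep (contig, category) pairs with category 0, 1 or 2."""
    return [(c, cat) for c, cat in categorized
            if AmgCategory(cat) <= AmgCategory.VIRAL_BOTH_SIDES]


# ---------------------------------------------------------------------------
# Host consensus
# ---------------------------------------------------------------------------

def _rank_component(taxonomy: str, rank: str) -> str:
    """Extract one rank from a lineage string; plain names pass through."""
    if taxonomy is None:
        return ""
    taxonomy = taxonomy.strip()
    if ";" not in taxonomy:
        return taxonomy
    parts = [p.strip() for p in taxonomy.split(";")]
    try:
        i = LINEAGE_RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}") from None
    return parts[i] if i < len(parts) else ""


def consensus_host(calls: dict, contig_id: str = "", rank: str = "phylum") -> HostCall:
    """Two-of-three consensus host assignment.

    ``calls`` maps tool name -> taxonomy string (lineage or plain name); a
    missing or empty entry never matches anything.  The host is assigned when
    at least two of the three tools agree at ``rank``; otherwise the call is
    ``"unassigned"`` with agreement level 0.
    """
    votes = {}
    for tool in HOST_TOOLS:
        tax = _rank_component(calls.get(tool), rank)
        if tax:
            votes.setdefault(tax, 0)
            votes[tax] += 1
    if votes:
        best, count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if count >= 2:
            return HostCall(contig_id, dict(calls), best, count)
    return HostCall(contig_id, dict(calls), "unassigned", 0)


# ---------------------------------------------------------------------------
# Tabular IO and the end-to-end report
# ---------------------------------------------------------------------------

def read_gene_table(path) -> list:
    """Read contigs from a tab-delimited per-gene annotation table.

    Expected header: contig_id, gene_index, start, end, strand, label
    (label = comma-separated annotation classes), plus optional columns
    contig_length and circular.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    contigs = []
    for cid, sub in df.groupby("contig_id", sort=False):
        sub = sub.sort_values("start", key=lambda s: s.astype(int))
        genes = []
        for _, row in sub.iterrows():
            labels = frozenset(
                x.strip() for x in str(row["label"]).split(",") if x.strip())
            genes.append(GeneRecord(cid, int(row["gene_index"]),
                                    int(row["start"]), int(row["end"]),
                                    row["strand"], labels))
        length = (int(sub["contig_length"].iloc[0])
                  if "contig_length" in sub.columns else max(g.end for g in genes))
        circular = (str(sub["circular"].iloc[0]).lower() in {"true", "1", "yes"}
                    if "circular" in sub.columns else False)
        contigs.append(AnnotatedContig(cid, length, genes, circular))
    return contigs


def read_hit_table(path) -> pd.DataFrame:
    return _validate_hit_table(pd.read_csv(path, sep="\t"))


def read_host_table(path) -> dict:
    """Read per-contig host predictions (columns: contig_id, tool, taxonomy)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {cid: dict(zip(sub["tool"], sub["taxonomy"]))
            for cid, sub in df.groupby("contig_id")}


def classify_contigs(contigs, host_calls=None, window=None,
                     rank: str = "phylum") -> pd.DataFrame:
    """Run categorisation + retention + host consensus over annotated contigs.

    Returns one row per AMG candidate gene with columns contig_id, amg_gene,
    category, retained, consensus_host, agreement_level.
    """
    host_calls = host_calls or {}
    rows = []
    for contig in contigs:
        for idx in contig.amg_indices():
            cat = categorize_amg(contig, idx, window=window)
            host = consensus_host(host_calls.get(contig.contig_id, {}),
                                  contig.contig_id, rank=rank)
            rows.append({
                "contig_id": contig.contig_id,
                "amg_gene": idx,
                "category": int(cat),
                "retained": cat <= AmgCategory.VIRAL_BOTH_SIDES,
                "consensus_host": host.consensus,
                "agreement_level": host.agreement_level,
            })
    return pd.DataFrame(rows, columns=["contig_id", "amg_gene", "category",
                                       "retained", "consensus_host",
                                       "agreement_level"])
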