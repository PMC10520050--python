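"""Small-RNA class calling and normalized per-gene quantification.

Three built-in rules:

* piRNA (21U-RNA): maps uniquely and perfectly in the sense orientation to a
  piRNA-producing locus, 5' T, 15-40 nt, with the 5' end at offset 0, 1, or 2
  from the locus's annotated 5' end (strand-aware).
* 22G-RNA: 21-23 nt, 5' G or A, with at least one alignment antisense to a
  protein-coding exon, pseudogene exon, lincRNA, rRNA, or transposon.
  Multi-mapping is allowed; each location receives ``count / n_hits`` and the
  location weight is split equally among the eligible features there, except
  that rRNA takes the whole location weight when it overlaps another feature.
* 26G-RNA: 25-27 nt, 5' G, antisense to protein-coding exons. The literature
  does not pin this class down as sharply as the other two, so the rule is
  fully configurable via :class:`ClassRule`.

Weights follow count x (1 / n_hits) x (1 / n_features_at_location); locations
overlapping no eligible feature contribute no weight, so the per-read weight
sum equals the read count exactly when every location lands on an eligible
feature (always true for unambiguously simulated reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import FeatureIndex
from .readproc import Alignment, CollapsedRead

G22_ELIGIBLE = frozenset(
    {"protein_coding", "pseudogene", "lincRNA", "rRNA", "transposon"}
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClassRule:
    """A small-RNA class definition."""

    name: str
    length_range: tuple[int, int]
    first_bases: frozenset[str]
    orientation: str  # "sense" | "antisense"
    unique_only: bool = False
    eligible_biotypes: frozenset[str] = frozenset()
    offset_window: int | None = None  # max 5'-end offset from the locus 5' end
    rrna_precedence: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"rule {self.name}: empty length range")
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"rule {self.name}: bad orientation")

    def length_ok(self, n: int) -> bool:
        return self.length_range[0] <= n <= self.length_range[1]


PIRNA_RULE = ClassRule(
    name="piRNA",
    length_range=(15, 40),
    first_bases=frozenset("T"),
    orientation="sense",
    unique_only=True,
    eligible_biotypes=frozenset({"piRNA_locus"}),
    offset_window=2,
)

G22_RULE = ClassRule(
    name="22G",
    length_range=(21, 23),
    first_bases=frozenset("GA"),
    orientation="antisense",
    eligible_biotypes=G22_ELIGIBLE,
    rrna_precedence=True,
)

G26_RULE = ClassRule(
    name="26G",
    length_range=(25, 27),
    first_bases=frozenset("G"),
    orientation="antisense",
    eligible_biotypes=frozenset({"protein_coding"}),
)

DEFAULT_RULES: tuple[ClassRule, ...] = (PIRNA_RULE, G22_RULE, G26_RULE)


@dataclass
class ClassifiedRead:
    read_id: str
    cls: str
    count: int
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values())


def _five_prime(aln: Alignment) -> int:
    return aln.start if aln.strand == "+" else aln.end - 1


def call_pirna(
    read: CollapsedRead,
    alignments: Sequence[Alignment],
    index: FeatureIndex,
    rule: ClassRule = PIRNA_RULE,
) -> ClassifiedRead | None:
    """Apply the piRNA rule; returns ``None`` on refusal."""
    if not alignments or not rule.length_ok(len(read.sequence)):
        return None
    if read.sequence[0] not in rule.first_bases:
        return None
    if rule.unique_only and alignments[0].n_hits != 1:
        return None
    for aln in alignments:
        loci = index.query(
            aln.contig,
            aln.start,
            aln.end,
            strand=aln.strand,  # sense: read strand equals locus strand
            biotypes=rule.eligible_biotypes,
        )
        p5 = _five_prime(aln)
        for locus in loci:
            offset = p5 - locus.start if locus.strand == "+" else locus.end - 1 - p5
            if 0 <= offset <= (rule.offset_window or 0):
                return ClassifiedRead(
                    read_id=read.id,
                    cls=rule.name,
                    count=read.count,
                    weights={locus.id: float(read.count) / alignments[0].n_hits},
                )
    return None


def _call_antisense(
    read: CollapsedRead,
    alignments: Sequence[Alignment],
    index: FeatureIndex,
    rule: ClassRule,
) -> ClassifiedRead | None:
    if not alignments or not rule.length_ok(len(read.sequence)):
        return None
    if read.sequence[0] not in rule.first_bases:
        return None
    if rule.unique_only and alignments[0].n_hits != 1:
        return None
    n_hits = alignments[0].n_hits
    weights: dict[str, float] = {}
    for aln in alignments:
        want_strand = (
            aln.strand if rule.orientation == "sense" else ("-" if aln.strand == "+" else "+")
        )
        feats = index.query_countable(
            aln.contig,
            aln.start,
            aln.end,
            strand=want_strand,
            biotypes=rule.eligible_biotypes,
        )
        if not feats:
            continue
        if rule.rrna_precedence:
            rrna = [f for f in feats if f.biotype == "rRNA"]
            if rrna:
                feats = rrna
        share = read.count / n_hits / len(feats)
        for f in feats:
            weights[f.id] = weights.get(f.id, 0.0) + share
    if not weights:
        return None
    return ClassifiedRead(read_id=read.id, cls=rule.name, count=read.count, weights=weights)


def call_22g(
    read: CollapsedRead,
    alignments: Sequence[Alignment],
    index: FeatureIndex,
    rule: ClassRule = G22_RULE,
) -> ClassifiedRead | None:
    return _call_antisense(read, alignments, index, rule)


def call_26g(
    read: CollapsedRead,
    alignments: Sequence[Alignment],
    index: FeatureIndex,
    rule: ClassRule = G26_RULE,
) -> ClassifiedRead | None:
    return _call_antisense(read, alignments, index, rule)


def _dispatch(
    read: CollapsedRead,
    alns: Sequence[Alignment],
    index: FeatureIndex,
    rule: ClassRule,
) -> ClassifiedRead | None:
    if rule.orientation == "sense" and rule.offset_window is not None:
        return call_pirna(read, alns, index, rule)
    return _call_antisense(read, alns, index, rule)


def classify_all(
    reads: Iterable[CollapsedRead],
    alignments_by_read: Mapping[str, Sequence[Alignment]],
    index: FeatureIndex,
    rules: Sequence[ClassRule] = DEFAULT_RULES,
) -> list[ClassifiedRead]:
    """Assign each read the first matching class in rule order, else unassigned.

    Rule order defaults to piRNA -> 22G -> 26G; the piRNA uniqueness + sense +
    5'T requirements make genuine overlap with the G classes essentially
    impossible, so the order is benign.
    """
    out: list[ClassifiedRead] = []
    for read in reads:
        alns = alignments_by_read.get(read.id, ())
        result = None
        for rule in rules:
            result = _dispatch(read, alns, index, rule)
            if result is not None:
                break
        if result is None:
            result = ClassifiedRead(read_id=read.id, cls=UNASSIGNED, count=read.count)
        out.append(result)
    return out


class GeneCountTable:
    """Per-gene, per-class fractional counts and RPM for one sample.

    RPM(gene, class) = 1e6 x raw(gene, class) / depth, where depth is the
    number of reads (raw occurrences, not weights) with at least one genomic
    alignment after structural filtering.
    """

    def __init__(self, df: pd.DataFrame, depth: int, sample: str = "sample") -> None:
        required = {"gene", "cls", "raw"}
        if not required.issubset(df.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        df = df.copy()
        df["rpm"] = 1e6 * df["raw"] / depth
        self.df = df.sort_values(["cls", "gene"]).reset_index(drop=True)
        self.depth = depth
        self.sample = sample

    def rpm(self, cls: str) -> pd.Series:
        sub = self.df[self.df["cls"] == cls]
        return sub.set_index("gene")["rpm"]

    def raw(self, cls: str) -> pd.Series:
        sub = self.df[self.df["cls"] == cls]
        return sub.set_index("gene")["raw"]

    def to_tsv(self, path: str) -> None:
        out = self.df.copy()
        out.insert(0, "sample", self.sample)
        out.to_csv(path, sep="\t", index=False)
        with open(path, "a") as fh:
            fh.write(f"# depth={self.depth}\n")

    @classmethod
    def read_tsv(cls, path: str) -> "GeneCountTable":
        depth = None
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("# depth="):
                depth = int(line.strip().removeprefix("# depth="))
        if depth is None:
            raise ValueError(f"{path}: missing '# depth=' footer")
        import io

        df = pd.read_csv(
            io.StringIO("".join(l for l in lines if not l.startswith("#"))), sep="\t"
        )
        sample = df["sample"].iloc[0] if len(df) else "sample"
        return cls(df.drop(columns=["sample", "rpm"]), depth=depth, sample=sample)


def quantify_genes(
    classified: Iterable[ClassifiedRead], depth: int, sample: str = "sample"
) -> GeneCountTable:
    """Sum per-read weights into a per-gene, per-class count table."""
    acc: dict[tuple[str, str], float] = {}
    for cr in classified:
        if cr.cls == UNASSIGNED:
            continue
        for gene, w in cr.weights.items():
            key = (gene, cr.cls)
            acc[key] = acc.get(key, 0.0) + w
    df = pd.DataFrame(
        [(g, c, r) for (g, c), r in acc.items()], columns=["gene", "cls", "raw"]
    )
    return GeneCountTable(df, depth=depth, sample=sample)


def length_firstnt_profile(
    reads: Iterable[tuple[str, int]] | Iterable[CollapsedRead],
    lengths: range = range(15, 41),
) -> pd.DataFrame:
    """Matrix of summed counts over (read length) x (5' base A/C/G/T).

    Accepts ``(sequence, count)`` pairs or :class:`CollapsedRead` objects.
    Margins reproduce the total read count for reads within the length range.
    """
    mat = pd.DataFrame(
        0, index=pd.Index(list(lengths), name="length"), columns=list("ACGT")
    )
    for item in reads:
        seq, count = (
            (item.sequence, item.count) if isinstance(item, CollapsedRead) else item
        )
        n = len(seq)
        if n in mat.index and seq[0] in mat.columns:
            mat.loc[n, seq[0]] += count
    return mat
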