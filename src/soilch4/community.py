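"""Amplicon count-table summaries: rarefaction, CH4-cycling guilds, CLAM.

Works on genus-level sample × taxon count tables with taxonomy lineage
strings. Provides seeded rarefaction without replacement (multivariate
hypergeometric), relative abundances, extraction of curated
methanogen/methanotroph guilds by taxonomy-token matching, and the CLAM
multinomial generalist/specialist classification implemented with exact
one-sided binomial tests against a supermajority threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountTable",
    "CuratedGuildList",
    "DEFAULT_GUILDS",
    "GuildExtraction",
    "NicheClassification",
    "rarefy",
    "relative_abundance",
    "extract_guilds",
    "clam_classify",
]


@dataclass(frozen=True)
class CountTable:
    """Sample × taxon integer counts with taxonomy and sample metadata.

    ``counts``: DataFrame, samples as rows, taxa as columns, non-negative
    integers. ``taxonomy``: Series mapping taxon id to a semicolon-separated
    rank-prefixed lineage string (``d__...;p__...;...;g__Genus``).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        missing = set(c.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxa without taxonomy: {sorted(missing)[:5]} ...")

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_taxa(self, taxa) -> "CountTable":
        taxa = [t for t in taxa if t in self.counts.columns]
        return CountTable(
            counts=self.counts[taxa],
            taxonomy=self.taxonomy.loc[taxa],
            metadata=self.metadata,
        )

    def subset_samples(self, samples) -> "CountTable":
        return CountTable(
            counts=self.counts.loc[samples],
            taxonomy=self.taxonomy,
            metadata=None if self.metadata is None else self.metadata.loc[samples],
        )

    def to_tsv(self, path) -> None:
        """Write taxa × samples TSV with a trailing taxonomy column."""
        out = self.counts.T.copy()
        out["taxonomy"] = self.taxonomy.reindex(out.index)
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: pd.DataFrame | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        tax = df.pop("taxonomy")
        return cls(counts=df.T.astype(int), taxonomy=tax, metadata=metadata)


def _norm(token: str) -> str:
    return token.strip().replace("_", " ").casefold()


@dataclass(frozen=True)
class CuratedGuildList:
    """Curated CH4-cycling taxa: methanogens (mcrABC) and methanotrophs
    (pmoCAB/mmoX), matched by name against any taxonomy rank token."""

    methanogens: tuple[str, ...]
    methanotrophs: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, lst in (("methanogens", self.methanogens),
                          ("methanotrophs", self.methanotrophs)):
            if any(not s for s in lst):
                raise ValueError(f"empty name in {name}")
            if len({_norm(s) for s in lst}) != len(lst):
                raise ValueError(f"duplicate names in {name}")
        both = {_norm(s) for s in self.methanogens} & {
            _norm(s) for s in self.methanotrophs
        }
        if both:
            raise ValueError(f"names in both guilds: {sorted(both)}")


DEFAULT_GUILDS = CuratedGuildList(
    methanogens=(
        "Methanobacterium",
        "Candidatus Methanomethylicus",
        "Methanobacteria",
        "Methanocella",
        "Methanomassiliicoccus",
        "Methanosaeta",
        "Methanosarcina",
        "Bathyarchaeia",
        "Thermoplasmatales",
    ),
    methanotrophs=(
        "Methylocystis",
        "Candidatus Methanoperedens",
        "Candidatus Methylospira",
        "Methylomirabilaceae",
        "Methylomonas",
        "Methylosinus",
        "Methylovirgula",
        "RCP2-54",
    ),
)


def _lineage_tokens(lineage: str) -> list[str]:
    toks = []
    for part in str(lineage).split(";"):
        part = part.strip()
        if "__" in part:
            part = part.split("__", 1)[1]
        if part:
            toks.append(_norm(part))
    return toks


def rarefy(
    table: CountTable, depth: int = 29_300, seed: int = 0
) -> tuple[CountTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and returned
    in the second element. Subsampling is multivariate hypergeometric and
    reproducible under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    kept = totals.index[totals >= depth]
    dropped = [str(s) for s in totals.index[totals < depth]]
    rows = []
    for s in kept:
        counts = table.counts.loc[s].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(
                rng.multivariate_hypergeometric(counts, depth, method="marginals")
            )
    new = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, table.counts.shape[1]), int),
        index=kept,
        columns=table.counts.columns,
    )
    meta = None if table.metadata is None else table.metadata.loc[kept]
    return CountTable(counts=new, taxonomy=table.taxonomy, metadata=meta), dropped


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1."""
    totals = table.sample_totals
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total samples: {bad}")
    return table.counts.div(totals, axis=0)


@dataclass(frozen=True)
class GuildExtraction:
    methanogens: CountTable
    methanotrophs: CountTable
    summed_relative_abundance: pd.DataFrame  # columns: methanogens, methanotrophs
    match_report: pd.DataFrame  # taxon, matched_name, guild


def extract_guilds(
    table: CountTable, guilds: CuratedGuildList = DEFAULT_GUILDS
) -> GuildExtraction:
    """Split out methanogen and methanotroph subtables by taxonomy match.

    A taxon joins a guild when any rank token of its lineage equals
    (case-insensitively, underscores as spaces) a curated guild name. Names
    may appear in only one guild (validated by :class:`CuratedGuildList`),
    so each matched taxon lands in exactly one subtable. Idempotent:
    re-extracting from a guild subtable returns it unchanged.
    """
    gen_names = {_norm(s): s for s in guilds.methanogens}
    oth_names = {_norm(s): s for s in guilds.methanotrophs}
    rows = []
    gens, oths = [], []
    for taxon in table.counts.columns:
        toks = _lineage_tokens(table.taxonomy.loc[taxon])
        hit_gen = next((gen_names[t] for t in toks if t in gen_names), None)
        hit_oth = next((oth_names[t] for t in toks if t in oth_names), None)
        if hit_gen:
            gens.append(taxon)
            rows.append({"taxon": taxon, "matched_name": hit_gen, "guild": "methanogen"})
        elif hit_oth:
            oths.append(taxon)
            rows.append({"taxon": taxon, "matched_name": hit_oth, "guild": "methanotroph"})
    rel = relative_abundance(table)
    summed = pd.DataFrame(
        {
            "methanogens": rel[gens].sum(axis=1) if gens else 0.0,
            "methanotrophs": rel[oths].sum(axis=1) if oths else 0.0,
        },
        index=table.counts.index,
    )
    return GuildExtraction(
        methanogens=table.subset_taxa(gens),
        methanotrophs=table.subset_taxa(oths),
        summed_relative_abundance=summed,
        match_report=pd.DataFrame(rows, columns=["taxon", "matched_name", "guild"]),
    )


@dataclass(frozen=True)
class NicheClassification:
    """Per-taxon CLAM labels and the parameters that produced them."""

    labels: pd.Series  # taxon -> generalist | specialist-A | specialist-B | too rare
    group_names: tuple[str, str]
    counts: dict  # label -> n taxa
    alpha: float
    individual_alpha: float
    specialization: float
    coverage_limit: int
    coverage_rule: str

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == len(self.labels)


def _pooled_totals(table) -> pd.Series:
    if isinstance(table, CountTable):
        return table.counts.sum(axis=0)
    if isinstance(table, pd.DataFrame):
        return table.sum(axis=0)
    return pd.Series(table)


def clam_classify(
    tableA,
    tableB,
    alpha: float = 0.05,
    specialization: float = 2.0 / 3.0,
    coverage_limit: int = 10,
    npoints: int = 20,
    adjust_alpha: bool = True,
    coverage_rule: str = "total",
    group_names: tuple[str, str] = ("A", "B"),
) -> NicheClassification:
    """CLAM multinomial niche classification of taxa between two habitats.

    Counts are pooled per taxon within each group (``yA``, ``yB``; group
    totals ``m``, ``n``). A taxon is a specialist of habitat A when the
    one-sided exact binomial test rejects, at the individual test level,
    the hypothesis that its relative abundance in A is at most
    ``u = specialization/(1-specialization)`` times that in B. Conditioning
    on the taxon's pooled total ``t`` makes the boundary null binomial:
    ``yA ~ Binomial(t, u·m/(u·m + n))`` (and symmetrically for B), which
    reduces to ``Binomial(t, specialization)`` for equal group totals. A
    taxon rejecting neither test is a generalist.

    ``adjust_alpha=True`` applies the published method's multiple-test
    allocation, dividing ``alpha`` by ``npoints`` (default 20) to set the
    individual test level; pass ``False`` to test each taxon at ``alpha``
    directly.

    Too-rare taxa are excluded from testing by ``coverage_rule``:
    ``"total"`` (default) needs pooled total ≥ ``coverage_limit``;
    ``"per_group"`` needs at least one group count ≥ ``coverage_limit``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.5 < specialization < 1:
        raise ValueError("specialization must be in (0.5, 1)")
    if coverage_rule not in ("total", "per_group"):
        raise ValueError("coverage_rule must be 'total' or 'per_group'")
    yA = _pooled_totals(tableA)
    yB = _pooled_totals(tableB)
    if not yA.index.equals(yB.index):
        raise ValueError("the two groups must share the same taxa")
    if (
        isinstance(tableA, CountTable)
        and isinstance(tableB, CountTable)
        and len(set(tableA.counts.index) & set(tableB.counts.index)) > 0
    ):
        raise ValueError("sample groups overlap")

    m = float(yA.sum())
    n = float(yB.sum())
    if m <= 0 or n <= 0:
        raise ValueError("both groups need positive totals")
    level = alpha / npoints if adjust_alpha else alpha
    u = specialization / (1.0 - specialization)
    qA = u * m / (u * m + n)  # boundary P(read is from A | taxon total)
    qB = u * n / (u * n + m)

    a = yA.to_numpy(dtype=np.int64)
    b = yB.to_numpy(dtype=np.int64)
    t = a + b
    if coverage_rule == "total":
        rare = t < coverage_limit
    else:
        rare = (a < coverage_limit) & (b < coverage_limit)

    # one-sided exact binomial tails P(Y >= y | t, q)
    p_specA = sps.binom.sf(a - 1, t, qA)
    p_specB = sps.binom.sf(b - 1, t, qB)
    labA, labB = (f"specialist-{g}" for g in group_names)
    labels = np.where(
        rare,
        "too rare",
        np.where(p_specA <= level, labA, np.where(p_specB <= level, labB, "generalist")),
    )
    ser = pd.Series(labels, index=yA.index, name="niche")
    counts = {
        lab: int((ser == lab).sum())
        for lab in ("generalist", labA, labB, "too rare")
    }
    return NicheClassification(
        labels=ser,
        group_names=group_names,
        counts=counts,
        alpha=alpha,
        individual_alpha=level,
        specialization=specialization,
        coverage_limit=coverage_limit,
        coverage_rule=coverage_rule,
    )
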