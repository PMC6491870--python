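"""Replicate QC, one-way ANOVA and Fisher's LSD for marker-trait association.

Enzyme-activity phenotypes (peroxidase activity of whole-wheat flour, in
U min^-1 g^-1) are assayed in duplicate; when the duplicate coefficient of
variation exceeds a threshold (default 10%) a third measurement resolves
the record and the mean of the two closest values is kept. Per-variety
means are then grouped by the allele call from the complementary STS
markers, per growing region and combined, and group differences are tested
by fixed-effects one-way ANOVA with Fisher's least-significant-difference
letters at the requested alpha levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeRecord",
    "ReplicateSet",
    "AnovaResult",
    "GroupSummary",
    "AssociationResult",
    "replicate_cv",
    "qc_mean",
    "one_way_anova",
    "fisher_lsd",
    "associate",
    "parse_phenotype_table",
]


@dataclass(frozen=True)
class PhenotypeRecord:
    """One variety's replicate activities within a region."""

    variety: str
    region: str
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        reps = tuple(float(r) for r in self.replicates)
        if len(reps) < 2:
            raise ValueError(f"{self.variety!r}: need at least 2 replicates")
        if any(r <= 0 for r in reps):
            raise ValueError(f"{self.variety!r}: activities must be positive")
        object.__setattr__(self, "replicates", reps)


@dataclass(frozen=True)
class ReplicateSet:
    """QC outcome for one record: CV, accepted mean and status."""

    values: tuple[float, ...]
    cv_pct: float
    qc_status: str  # pass | retested | fail
    accepted_mean: float | None


def replicate_cv(values) -> float:
    """Coefficient of variation of replicates, percent (sample SD / mean)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * arr.std(ddof=1) / mean


def qc_mean(record: PhenotypeRecord, cv_threshold: float = 10.0) -> ReplicateSet:
    """Apply the duplicate-CV rule and return the accepted mean.

    A two-value record is the duplicate itself: CV <= threshold accepts the
    mean (``pass``); above threshold with no third measurement the record
    fails. A record carrying a third value exists because the duplicate
    triggered a retest; it is resolved to the mean of the two closest values
    (``retested``), which discards the aberrant measurement. The outcome is
    invariant under replicate order; reported CV is over all values held.
    """
    values = tuple(sorted(record.replicates))
    cv = replicate_cv(values)
    if len(values) == 2:
        if cv <= cv_threshold:
            return ReplicateSet(values, cv, "pass", float(np.mean(values)))
        return ReplicateSet(values, cv, "fail", None)
    # closest pair among all replicates (sorted, so adjacent pairs suffice)
    gaps = [(values[i + 1] - values[i], i) for i in range(len(values) - 1)]
    _, i = min(gaps)
    return ReplicateSet(values, cv, "retested", float((values[i] + values[i + 1]) / 2))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    group_sizes: tuple[int, ...]
    group_means: tuple[float, ...]


def one_way_anova(groups: list) -> AnovaResult:
    """Fixed-effects one-way ANOVA for >= 2 groups of unequal sizes.

    Degenerate panels are handled explicitly: zero within-group variance
    gives F = 0 (equal means) or an infinite F with p = 0 (unequal means).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_w = int(ns.sum()) - len(arrays)
    msw = ssw / df_w
    if ssw == 0.0:
        if ssb == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
    else:
        f = (ssb / df_b) / msw
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=f,
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        ms_within=msw,
        group_sizes=tuple(int(n) for n in ns),
        group_means=tuple(float(m) for m in means),
    )


def fisher_lsd(
    groups: list, alpha: float = 0.05, labels: list[str] | None = None
) -> dict:
    """Fisher's protected LSD letters after one-way ANOVA.

    The pairwise threshold is ``t(1 - alpha/2, df_w) * sqrt(MSW * (1/n_i +
    1/n_j))``; letters are assigned by the standard descending-mean grouping
    (groups sharing a letter are not significantly different). A single
    group gets the single letter "a".
    """
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    if len(groups) == 1:
        return {"letters": {labels[0]: "a"}, "lsd": {}, "anova": None}
    anova = one_way_anova(groups)
    tcrit = stats.t.ppf(1 - alpha / 2, anova.df_within)
    order = sorted(
        range(len(groups)), key=lambda i: -anova.group_means[i]
    )  # descending means
    lsd: dict[tuple[str, str], float] = {}
    differs: dict[tuple[int, int], bool] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            thresh = tcrit * math.sqrt(
                anova.ms_within * (1 / anova.group_sizes[i] + 1 / anova.group_sizes[j])
            )
            lsd[(labels[i], labels[j])] = thresh
            diff = abs(anova.group_means[i] - anova.group_means[j]) > thresh
            differs[(i, j)] = differs[(j, i)] = diff
    # letter assignment: walk groups by descending mean; reuse a letter set
    # when the group is indistinguishable from every member
    letter_sets: list[list[int]] = []
    for g in order:
        placed = False
        for members in letter_sets:
            if all(not differs[(g, m)] for m in members):
                members.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    letters = {labels[i]: "" for i in range(len(groups))}
    for letter_idx, members in enumerate(letter_sets):
        for g in members:
            letters[labels[g]] += chr(ord("a") + letter_idx)
    return {"letters": letters, "lsd": lsd, "anova": anova}


@dataclass(frozen=True)
class GroupSummary:
    region: str
    allele: str
    n: int
    mean: float
    min: float
    max: float
    letters: dict[float, str] = field(default_factory=dict)  # alpha -> letter


@dataclass
class AssociationResult:
    """Marker-trait association over a genotyped, phenotyped variety panel."""

    summaries: list[GroupSummary]
    anova: dict  # (region|"combined") -> AnovaResult | None
    letters: dict  # (region, alpha) -> {allele: letter}
    n_excluded: int
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "region": s.region,
                    "genotype": s.allele,
                    "n": s.n,
                    "mean": round(s.mean, 1),
                    "range": f"{s.min:.1f}-{s.max:.1f}",
                    **{
                        f"sig_{alpha:g}": s.letters.get(alpha, "")
                        for alpha in sorted({a for _, a in self.letters})
                    },
                }
            )
        return pd.DataFrame(rows)


def parse_phenotype_table(source) -> list[PhenotypeRecord]:
    """Read a phenotype CSV/TSV: ``variety,region,rep1,rep2[,rep3]``."""
    from .stock_panel import _read_table

    df = _read_table(source)
    df.columns = [c.strip().lower() for c in df.columns]
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not {"variety", "region"}.issubset(df.columns) or len(rep_cols) < 2:
        raise ValueError(
            "phenotype table needs columns variety, region, rep1, rep2[, rep3]"
        )
    records = []
    for _, row in df.iterrows():
        reps = [
            float(row[c])
            for c in rep_cols
            if not pd.isna(row[c]) and str(row[c]).strip() != ""
        ]
        records.append(
            PhenotypeRecord(
                variety=str(row["variety"]).strip(),
                region=str(row["region"]).strip(),
                replicates=tuple(reps),
            )
        )
    return records


def associate(
    calls: dict[str, str],
    phenotypes: list[PhenotypeRecord],
    alphas: tuple[float, ...] = (0.05, 0.01),
    cv_threshold: float = 10.0,
) -> AssociationResult:
    """Associate allele calls with phenotype means, per region and combined.

    ``calls`` maps variety -> allele label; varieties with "ambiguous" or
    "null" calls (or failing replicate QC) are excluded and counted. Each
    region with both allele classes is tested by ANOVA; single-class regions
    are summarized with a note. The combined analysis pools regions on
    per-variety means.
    """
    notes: list[str] = []
    n_excluded = 0
    rows = []
    for rec in phenotypes:
        allele = calls.get(rec.variety)
        if allele is None:
            raise ValueError(f"variety {rec.variety!r} has no genotype call")
        if allele in ("ambiguous", "null"):
            n_excluded += 1
            continue
        qc = qc_mean(rec, cv_threshold=cv_threshold)
        if qc.accepted_mean is None:
            n_excluded += 1
            notes.append(f"{rec.variety}: replicate QC failed (CV {qc.cv_pct:.1f}%)")
            continue
        rows.append(
            {
                "variety": rec.variety,
                "region": rec.region,
                "allele": allele,
                "mean": qc.accepted_mean,
                "qc": qc.qc_status,
            }
        )
    df = pd.DataFrame(rows)
    summaries: list[GroupSummary] = []
    anova_out: dict = {}
    letters_out: dict = {}
    if df.empty:
        return AssociationResult([], {}, {}, n_excluded, notes + ["no usable varieties"])

    scopes = [(r, df[df["region"] == r]) for r in sorted(df["region"].unique())]
    scopes.append(("combined", df))
    for scope, sub in scopes:
        alleles = sorted(sub["allele"].unique())
        groups = [sub.loc[sub["allele"] == a, "mean"].to_numpy() for a in alleles]
        scope_summaries = [
            GroupSummary(
                region=scope,
                allele=a,
                n=len(g),
                mean=float(np.mean(g)),
                min=float(np.min(g)),
                max=float(np.max(g)),
            )
            for a, g in zip(alleles, groups)
        ]
        if len(alleles) < 2 or any(len(g) < 2 for g in groups):
            anova_out[scope] = None
            notes.append(f"{scope}: only one allele class (or group too small); test skipped")
            for alpha in alphas:
                letters_out[(scope, alpha)] = {a: "a" for a in alleles}
        else:
            anova_out[scope] = one_way_anova(groups)
            for alpha in alphas:
                letters_out[(scope, alpha)] = fisher_lsd(groups, alpha, labels=alleles)[
                    "letters"
                ]
        for s in scope_summaries:
            s.letters.update(
                {alpha: letters_out[(scope, alpha)].get(s.allele, "") for alpha in alphas}
            )
        summaries.extend(scope_summaries)
    return AssociationResult(
        summaries=summaries,
        anova=anova_out,
        letters=letters_out,
        n_excluded=n_excluded,
        notes=notes,
    )
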