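"""Stem-loop RT-qPCR primer construction and relative-expression analysis.

cDNA synthesis of a mature miRNA uses a stem-loop RT primer: a 44-nt
conserved backbone plus six variable 3' nucleotides complementary to the
miRNA's 3' end.  The forward PCR primer is the mature sequence itself
(as DNA); the reverse primer is universal, a substring of the backbone.
Relative expression is quantified by the 2^-ddCt method against the
arithmetic mean Ct of the reference genes, and condition pairs are
compared with Welch's two-tailed t-test on per-replicate dCt values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp_dna, to_dna
from .config import DEFAULT_CONFIG, PipelineConfig

log = logging.getLogger(__name__)

#: 44 conserved nucleotides of the stem-loop RT primer; the six variable
#: positions appended to it are complementary to the miRNA 3' terminus.
STEM_LOOP_BACKBONE = "GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC"
UNIVERSAL_REVERSE_PRIMER = "GTGCAGGGTCCGAGGT"


@dataclass(frozen=True)
class PrimerSet:
    mirna_id: str
    forward: str          # DNA copy of the mature sequence
    stem_loop_rt: str     # 44-nt backbone + 6-nt variable tail
    universal_reverse: str = UNIVERSAL_REVERSE_PRIMER

    @property
    def tail(self) -> str:
        return self.stem_loop_rt[len(STEM_LOOP_BACKBONE):]


def design_primers(mature: str, mirna_id: str = "query") -> PrimerSet:
    """Primer set for one mature miRNA.

    The variable tail is the DNA reverse complement of the mature's
    3'-terminal six nucleotides.
    """
    if len(mature) < 6:
        raise ValueError("mature sequence must be at least 6 nt")
    dna = to_dna(mature)
    return PrimerSet(
        mirna_id=mirna_id,
        forward=dna,
        stem_loop_rt=STEM_LOOP_BACKBONE + revcomp_dna(dna[-6:]),
    )


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    condition_a: str
    condition_b: str
    delta_ct_a: float        # mean dCt in condition A
    delta_ct_b: float
    ddct: float              # dCt(A) - dCt(B)
    rq: float                # 2^-ddct, expression of A relative to B
    t_statistic: float
    p_value: float
    significant: bool


def _delta_ct(
    ct: pd.DataFrame, gene: str, reference_genes: list[str], condition: str
) -> np.ndarray:
    """Per-replicate dCt = Ct(target) - mean Ct(references)."""
    sub = ct[ct["condition"] == condition]
    target = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    if target.empty:
        raise ValueError(f"no Ct values for {gene!r} in condition {condition!r}")
    refs = []
    for ref in reference_genes:
        r = sub[sub["gene"] == ref].set_index("replicate")["ct"]
        if r.empty:
            raise ValueError(f"missing reference gene {ref!r} in {condition!r}")
        refs.append(r)
    ref_mean = pd.concat(refs, axis=1).mean(axis=1)
    common = target.index.intersection(ref_mean.index)
    return (target.loc[common] - ref_mean.loc[common]).to_numpy()


def relative_expression(
    ct: pd.DataFrame,
    gene: str,
    reference_genes: list[str],
    condition_a: str,
    condition_b: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ExpressionResult:
    """2^-ddCt relative quantity of ``gene`` in A versus B with Welch's test.

    ``ct`` has columns (gene, condition, replicate, ct).  With a single
    replicate the quantity is still computed but the test is skipped.
    """
    dct_a = _delta_ct(ct, gene, reference_genes, condition_a)
    dct_b = _delta_ct(ct, gene, reference_genes, condition_b)
    ddct = float(dct_a.mean() - dct_b.mean())
    rq = 2.0 ** (-ddct)
    if len(dct_a) >= 2 and len(dct_b) >= 2:
        t_stat, p = stats.ttest_ind(dct_a, dct_b, equal_var=False)
        t_stat, p = float(t_stat), float(p)
    else:
        log.warning("single replicate for %s: t-test skipped", gene)
        t_stat, p = math.nan, math.nan
    return ExpressionResult(
        gene=gene,
        condition_a=condition_a,
        condition_b=condition_b,
        delta_ct_a=float(dct_a.mean()),
        delta_ct_b=float(dct_b.mean()),
        ddct=ddct,
        rq=rq,
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < config.alpha) if not math.isnan(p) else False,
    )


#: The four comparisons drawn per stress panel, with their significance codes:
#: '*' control vs control between genotypes, 'a' control vs stress in the
#: sensitive/susceptible genotype, 'b' control vs stress in the
#: tolerant/resistant genotype, '1' stressed vs stressed between genotypes.
COMPARISON_PANELS = {
    "drought": (
        ("*", "DSRC", "DTRC"),
        ("a", "DSRT", "DSRC"),
        ("b", "DTRT", "DTRC"),
        ("1", "DSRT", "DTRT"),
    ),
    "rust": (
        ("*", "RSLC", "RRLC"),
        ("a", "RSLT", "RSLC"),
        ("b", "RRLT", "RRLC"),
        ("1", "RSLT", "RRLT"),
    ),
}


def expression_report(
    ct: pd.DataFrame,
    target_genes: list[str],
    reference_genes: list[str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Comparison table across the eight libraries for each target gene.

    One row per (gene, stress, code); the ``labels`` of a gene/stress is
    the concatenation of codes whose comparison is significant at alpha.
    """
    rows = []
    for gene in target_genes:
        for stress, panel in COMPARISON_PANELS.items():
            for code, cond_a, cond_b in panel:
                res = relative_expression(
                    ct, gene, reference_genes, cond_a, cond_b, config
                )
                rows.append(
                    {
                        "gene": gene,
                        "stress": stress,
                        "code": code,
                        "condition_a": cond_a,
                        "condition_b": cond_b,
                        "rq": res.rq,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)


def significance_labels(report: pd.DataFrame) -> pd.DataFrame:
    """Collapse a report to one row per (gene, stress) with its label string."""
    rows = []
    for (gene, stress), grp in report.groupby(["gene", "stress"], sort=True):
        labels = "".join(sorted(grp.loc[grp["significant"], "code"]))
        rows.append({"gene": gene, "stress": stress, "labels": labels})
    return pd.DataFrame(rows)


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["gene", "condition", "replicate", "ct"]
    if list(df.columns) != expected:
        raise ValueError(f"Ct table must have columns {expected}")
    if not (np.isfinite(df["ct"]).all() and (df["ct"] > 0).all()):
        raise ValueError("Ct values must be finite and positive")
    return df
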