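"""Scoring of pipeline output against simulator truth.

Detection is scored per (sample, catalogued allele) pair: a pair is positive
in truth when the sample carries at least one copy of the allele, and
positive in the calls when the annotation stage reported it. Concordance is
stricter: the full catalog diplotype (allele set with zygosity) must match
truth exactly, per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import SampleResult
from .simulate import AlleleCatalog, TruthSet


@dataclass
class DetectionScore:
    tp: int
    fn: int
    fp: int
    tn: int
    n_pairs: int

    @property
    def sensitivity(self) -> float:
        """Percent of carried alleles detected (100 x TP / (TP + FN))."""
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        """Percent of non-carried alleles correctly not called (100 x TN / (TN + FP))."""
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def score_catalog_detection(
    results: dict[str, SampleResult],
    truth: TruthSet,
    catalog: AlleleCatalog,
) -> DetectionScore:
    """Sensitivity/specificity of catalogued-allele detection over all samples."""
    names = catalog.names
    truth_by_id = truth.by_id()
    tp = fn = fp = tn = 0
    for sid, res in results.items():
        t = truth_by_id[sid].catalog_dosage
        called = {a.allele_name for a in res.annotations}
        for name in names:
            has = t.get(name, 0) > 0
            got = name in called
            if has and got:
                tp += 1
            elif has and not got:
                fn += 1
            elif not has and got:
                fp += 1
            else:
                tn += 1
    return DetectionScore(tp, fn, fp, tn, tp + fn + fp + tn)


def diplotype_concordance(
    results: dict[str, SampleResult],
    truth: TruthSet,
    catalog: AlleleCatalog,
) -> tuple[float, list[str]]:
    """Percent of samples whose catalog diplotype (with zygosity) equals truth.

    Returns the concordance and the list of discordant sample ids.
    """
    names = set(catalog.names)
    truth_by_id = truth.by_id()
    bad = [
        sid
        for sid, res in results.items()
        if res.diplotype(names) != truth_by_id[sid].diplotype(names)
    ]
    pct = 100.0 * (len(results) - len(bad)) / len(results) if results else float("nan")
    return pct, sorted(bad)
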