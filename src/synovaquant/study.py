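"""Packaged per-patient study table and headline reproduction.

The 7 T knee-synovitis feasibility cohort (n = 10, psoriatic or
rheumatoid arthritis) published its per-patient semiquantitative
scores, synovial volumes and DCE parameter means, together with the
reader-agreement estimates, in a single table. That table is packaged
here as two checksum-verified CSV fixtures, and
:func:`reproduce_headline` recomputes the cohort's derivable headline
numbers from the per-patient rows through the scoring, volumetry and
reliability modules, reporting each next to its published value.

Not reproducible from the table and therefore excluded: the kappa/ICC
point values themselves (the raw two-reader data are unpublished),
per-patient severity labels (internally inconsistent with the printed
banding rule for one patient), and TTP summaries (the table's TTP unit
is ambiguous; values are stored exactly as printed).
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

from .reliability import AgreementResult, band_tally, interpret_icc, interpret_kappa
from .scoring import ScoreSheet, categorize_severity, cohort_summary
from .volumetry import paired_compare

#: Published cohort-level values the fixture can reproduce.
PUBLISHED = {
    "peripatellar_mean_ce": 3.3,
    "peripatellar_sd_ce": 1.6,
    "peripatellar_mean_flair": 2.4,
    "peripatellar_sd_flair": 1.6,
    "pearson_r_scores": 0.938,
    "pearson_r_volumes": 0.948,
    "percent_volume_diff_mean": 18.6,
    "percent_volume_diff_sd": 9.5,
    "wash_in_mean": 1.46,
    "iauc_mean": 1.08,
    "icc_excellent_count": 8,
    "icc_good_count": 6,
    "severity_mild_count": 3,
    "severity_moderate_count": 5,
    "severity_severe_count": 2,
}


@dataclass
class StudyTable:
    """The packaged per-patient table plus printed agreement estimates."""

    patients: pd.DataFrame
    agreement: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.patients) != 10:
            raise ValueError("the study table must contain exactly 10 patients")
        if (self.patients[["volume_ce_cm3", "volume_flair_cm3"]] <= 0).any().any():
            raise ValueError("volumes must be positive")
        for col, hi in (
            ("hoffa_grade", 3),
            ("effusion_grade", 3),
            ("peripatellar_ce", 6),
            ("peripatellar_flair", 6),
            ("whole_knee_sum", 33),
        ):
            vals = self.patients[col]
            if ((vals < 0) | (vals > hi)).any():
                raise ValueError(f"{col} outside 0..{hi}")


def _read_verified(name: str) -> pd.DataFrame:
    data_dir = resources.files("synovaquant") / "data"
    raw = (data_dir / name).read_bytes()
    checksums = json.loads((data_dir / "checksums.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise RuntimeError(
            f"study fixture {name} is corrupted (sha256 {digest[:12]}… does not "
            f"match the packaged checksum)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixture() -> StudyTable:
    """Load the packaged study table, verifying file checksums."""
    return StudyTable(
        patients=_read_verified("study_patients.csv"),
        agreement=_read_verified("study_agreement.csv"),
    )


def _peripatellar_sheets(table: StudyTable, column: str, sequence: str):
    """Route the per-patient peripatellar sums through the scoring module.

    Only the two-site sum is published, so it is split into a
    medial/lateral pair preserving the sum; cohort statistics depend on
    the sums only.
    """
    sheets = []
    for _, row in table.patients.iterrows():
        total = int(row[column])
        sheets.append(
            ScoreSheet(
                patient_id=str(row["patient"]),
                sequence=sequence,
                site_grades={
                    "medial_peripatellar": (total + 1) // 2,
                    "lateral_peripatellar": total // 2,
                },
            )
        )
    return sheets


def reproduce_headline(table: StudyTable | None = None) -> dict:
    """Recompute the cohort's derivable headline numbers.

    Returns a report mapping each quantity to its computed value, the
    published value, and their absolute deviation; quantities without a
    published counterpart carry only the computed value.
    """
    if table is None:
        table = load_fixture()
    pt = table.patients

    ce = cohort_summary(
        _peripatellar_sheets(table, "peripatellar_ce", "T1-FS CE"), "T1-FS CE"
    )
    fl = cohort_summary(
        _peripatellar_sheets(table, "peripatellar_flair", "FLAIR-FS"), "FLAIR-FS"
    )
    r_scores = stats.pearsonr(pt["peripatellar_ce"], pt["peripatellar_flair"])
    t_scores = stats.ttest_rel(pt["peripatellar_ce"], pt["peripatellar_flair"])

    vol = paired_compare(
        list(zip(pt["volume_ce_cm3"], pt["volume_flair_cm3"])),
        patient_ids=[str(p) for p in pt["patient"]],
    )

    icc_results = [
        AgreementResult("icc", row.estimate, row.ci_low, row.ci_high,
                        {"source": "published"}, interpret_icc(row.estimate))
        for row in table.agreement.itertuples()
        if row.statistic == "icc"
    ]
    kappa_results = [
        AgreementResult("weighted_kappa", row.estimate, row.ci_low, row.ci_high,
                        {"source": "published"}, interpret_kappa(row.estimate))
        for row in table.agreement.itertuples()
        if row.statistic == "weighted_kappa"
    ]
    tally = band_tally(icc_results + kappa_results)

    def entry(computed: float, published_key: str | None = None) -> dict:
        out = {"computed": float(computed)}
        if published_key is not None:
            printed = PUBLISHED[published_key]
            out["published"] = printed
            out["abs_dev"] = abs(float(computed) - printed)
        return out

    return {
        "peripatellar_mean_ce": entry(ce.peripatellar_mean, "peripatellar_mean_ce"),
        "peripatellar_sd_ce": entry(ce.peripatellar_sd, "peripatellar_sd_ce"),
        "peripatellar_mean_flair": entry(
            fl.peripatellar_mean, "peripatellar_mean_flair"
        ),
        "peripatellar_sd_flair": entry(fl.peripatellar_sd, "peripatellar_sd_flair"),
        "pearson_r_scores": entry(r_scores.statistic, "pearson_r_scores"),
        "pearson_r_volumes": entry(vol.pearson_r, "pearson_r_volumes"),
        "percent_volume_diff_mean": entry(
            vol.percent_diff_mean, "percent_volume_diff_mean"
        ),
        "percent_volume_diff_sd": entry(
            vol.percent_diff_sd, "percent_volume_diff_sd"
        ),
        "percent_volume_diff_ce_denom_mean": entry(vol.percent_diff_ce_denom_mean),
        "volume_t_statistic": entry(vol.t_statistic),
        "volume_t_p_value": entry(vol.p_value),
        "score_t_p_value": entry(t_scores.pvalue),
        "wash_in_mean": entry(pt["wash_in_mean"].mean(), "wash_in_mean"),
        "wash_out_mean": entry(pt["wash_out_mean"].mean()),
        "pe_mean": entry(pt["pe_mean"].mean()),
        "iauc_mean": entry(pt["iauc_mean"].mean(), "iauc_mean"),
        "icc_excellent_count": entry(
            tally["icc"]["counts"]["excellent"], "icc_excellent_count"
        ),
        "icc_good_count": entry(tally["icc"]["counts"]["good"], "icc_good_count"),
        "kappa_band_counts": {
            k: int(v) for k, v in tally["weighted_kappa"]["counts"].items()
        },
        "severity_rule_counts": dict(
            Counter(categorize_severity(int(s)) for s in pt["whole_knee_sum"])
        ),
    }
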