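"""Whole-knee synovitis scoring: site grades to severity category.

Builds one patient's score sheet, sums the 11-site instrument, bands
the sum into a severity category, and shows the thickness-to-grade rule
used for the upper grades.
"""

from synovaquant import ScoreSheet, categorize_severity, grade_from_thickness
from synovaquant.scoring import peripatellar_sum, sum_whole_knee

sheet = ScoreSheet(
    patient_id="P1",
    sequence="T1-FS CE",
    site_grades={
        "medial_peripatellar": 2, "lateral_peripatellar": 3,
        "suprapatellar": 2, "infrapatellar": 1, "intercondylar": 2,
        "medial_perimeniscal": 1, "lateral_perimeniscal": 0,
        "acl_adjacent": 1, "pcl_adjacent": 0,
        "bakers_cyst": 2,  # optional site, present in this knee
    },
    hoffa_grade=1,
    effusion_grade=3,
)

total = sum_whole_knee(sheet)
print(f"whole-knee summed score: {total} (0-33 scale)")
print(f"severity category: {categorize_severity(total)}")
print(f"peripatellar sub-score: {peripatellar_sum(sheet)} (0-6 scale)")
print()
for mm in (5.5, 4.5, 3.0, 1.0):
    print(f"synovial thickness {mm:.1f} mm -> grade "
          f"{grade_from_thickness(mm)}")
print()
print("grades 2 and 3 are defined by thickness (>4-5 mm and >5 mm); the")
print("summed score bands are 0-5 normal/equivocal, 6-9 mild, 10-13")
print("moderate, >=14 severe.")
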