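"""Frozen reference subgroup tables for the metrics regression suite.

Published subgroup confusion counts (TP/TN/FP/FN) from a large ED
admission-prediction evaluation (~47k visits), together with the 2-decimal
precision / recall / accuracy / majority-accuracy cells printed alongside
them.  The suite asserts that our metric arithmetic reproduces every
printed cell from the raw counts.

Two specialty rows carry ``majority_discordant=True``: their printed
majority-accuracy cells (0.77 and 0.70) do not equal the larger class share
computed from their own printed counts (0.58 and 0.62), while every other
row's does.  Those two cells are excluded from the majority-accuracy
assertion; the counts-based metrics of those rows are still checked.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceRow:
    dimension: str
    level: str
    n: int
    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    majority_accuracy: float
    majority_discordant: bool = False


REFERENCE_ROWS = [
    # age groups
    ReferenceRow("age_group", "18-27", 4658, 346, 3561, 338, 413, 0.51, 0.46, 0.84, 0.84),
    ReferenceRow("age_group", "28-37", 5312, 536, 3689, 452, 635, 0.54, 0.46, 0.80, 0.78),
    ReferenceRow("age_group", "38-47", 4730, 675, 3058, 531, 466, 0.56, 0.59, 0.79, 0.76),
    ReferenceRow("age_group", "48-57", 6064, 1418, 3153, 903, 590, 0.61, 0.71, 0.75, 0.67),
    ReferenceRow("age_group", "58-67", 7330, 2484, 2991, 1297, 558, 0.66, 0.82, 0.75, 0.58),
    ReferenceRow("age_group", "68-77", 9437, 4257, 2848, 1713, 619, 0.71, 0.87, 0.75, 0.52),
    ReferenceRow("age_group", "78-87", 7444, 3806, 1951, 1265, 422, 0.75, 0.90, 0.77, 0.57),
    ReferenceRow("age_group", "≥88", 2332, 1265, 590, 349, 128, 0.78, 0.91, 0.80, 0.60),
    # medical specialties
    ReferenceRow("specialty", "Obstetrics and gynecology", 1003, 126, 648, 65, 164, 0.66, 0.43, 0.77, 0.71),
    ReferenceRow("specialty", "Urology", 1931, 658, 791, 247, 235, 0.73, 0.74, 0.75, 0.54),
    ReferenceRow("specialty", "Orthopedics", 1878, 242, 1411, 127, 98, 0.66, 0.71, 0.88, 0.82),
    ReferenceRow("specialty", "Neurology", 4659, 1543, 1338, 1438, 340, 0.52, 0.82, 0.62, 0.60),
    ReferenceRow("specialty", "Gastrointestinal and liver diseases", 2502, 1436, 321, 618, 127, 0.70, 0.92, 0.70, 0.70, True),
    ReferenceRow("specialty", "Pulmonology", 6068, 3170, 1519, 1034, 345, 0.75, 0.90, 0.77, 0.77, True),
    ReferenceRow("specialty", "Otorhinolaryngology", 643, 38, 512, 26, 67, 0.59, 0.36, 0.86, 0.84),
    ReferenceRow("specialty", "Internal medicine", 7810, 3598, 2342, 1399, 471, 0.72, 0.88, 0.76, 0.52),
    ReferenceRow("specialty", "Surgery", 17720, 2852, 11758, 1290, 1820, 0.69, 0.61, 0.82, 0.74),
    ReferenceRow("specialty", "Cardiology", 916, 471, 154, 265, 26, 0.64, 0.95, 0.68, 0.54),
    # triage urgency
    ReferenceRow("triage", "Unknown", 1355, 322, 865, 93, 75, 0.78, 0.81, 0.88, 0.71),
    ReferenceRow("triage", "U0", 178, 170, 0, 6, 2, 0.97, 0.99, 0.96, 0.97),
    ReferenceRow("triage", "U1", 4257, 2442, 529, 1172, 114, 0.68, 0.96, 0.70, 0.60),
    ReferenceRow("triage", "U2", 18403, 8077, 5670, 3253, 1403, 0.71, 0.85, 0.75, 0.52),
    ReferenceRow("triage", "U3", 17362, 3170, 10731, 1829, 1632, 0.63, 0.66, 0.80, 0.72),
    ReferenceRow("triage", "U4", 5733, 603, 4032, 494, 604, 0.55, 0.50, 0.81, 0.79),
    ReferenceRow("triage", "U5", 19, 3, 14, 1, 1, 0.75, 0.75, 0.89, 0.79),
    # arrival period
    ReferenceRow("part_of_day", "night", 3311, 1300, 1175, 637, 199, 0.67, 0.87, 0.75, 0.55),
    ReferenceRow("part_of_day", "morning", 11251, 3259, 5280, 1637, 1075, 0.67, 0.75, 0.76, 0.61),
    ReferenceRow("part_of_day", "afternoon", 22093, 6696, 10582, 3061, 1754, 0.69, 0.79, 0.78, 0.62),
    ReferenceRow("part_of_day", "evening", 10652, 3532, 4804, 1513, 803, 0.70, 0.81, 0.78, 0.59),
]

# Overall admitted fraction implied by the arrival-period rows (the four
# periods partition the cohort): sum(TP+FN) / sum(n) = 18618 / 47307.
POD_ROWS = [r for r in REFERENCE_ROWS if r.dimension == "part_of_day"]
REFERENCE_PREVALENCE = sum(r.tp + r.fn for r in POD_ROWS) / sum(r.n for r in POD_ROWS)
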