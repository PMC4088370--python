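"""Published zone statistics of the human interaction networks.

Reported values for the human functional protein interaction network
(HFPIN), the human signalling network (HSN) and their non-redundant merge
(CN), as published for the metric-space zone analysis: per-zone node
counts, and per-zone membership counts of curated annotation classes
(essential-ortholog, disease-associated, approved drug target, oncogene,
tumour suppressor) and of consistently-expressed gene sets across 13
cancer types.  These are inputs for arithmetic reproduction checks — the
original network files are not redistributed, so only the printed counts
can be recomputed into percentages and test statistics here.
"""

from __future__ import annotations

# Network-level summary: nodes, edges, diameter, centre protein.
HFPIN_SUMMARY = {"nodes": 9448, "edges": 181706, "diameter": 13, "centre": "MAPK14"}
HSN_SUMMARY = {"nodes": 6291, "edges": 62737, "diameter": 11, "centre": "MAPK1"}
CN_SUMMARY = {"nodes": 10573, "edges": 210689, "diameter": 13, "centre": "MAPK3"}

# Per-zone node counts (zone index -> nodes in zone).
HFPIN_ZONE_SIZES = {1: 374, 2: 4610, 3: 3464, 4: 578, 5: 104, 6: 14, 7: 2, 8: 1, 9: 1}
HSN_ZONE_SIZES = {1: 431, 2: 3527, 3: 1929, 4: 206, 5: 38, 6: 4}
CN_ZONE_SIZES = {1: 542, 2: 6011, 3: 3352, 4: 367, 5: 61, 6: 4, 7: 1, 8: 1, 9: 1}

# Annotation-class membership counts per HFPIN zone.
HFPIN_ESSENTIAL = {1: 161, 2: 1002, 3: 392, 4: 55, 5: 10}
HFPIN_DISEASE = {1: 159, 2: 1184, 3: 545, 4: 85, 5: 19, 6: 2}
HFPIN_DRUG_TARGET = {1: 59, 2: 346, 3: 77, 4: 11, 5: 3, 6: 1}
HFPIN_ONCOGENE = {1: 15, 2: 32, 3: 1, 4: 1}
HFPIN_TUMOUR_SUPPRESSOR = {1: 14, 2: 42, 3: 4, 4: 2}

# Annotation-class membership counts per HSN zone.
HSN_ESSENTIAL = {1: 157, 2: 815, 3: 268, 4: 29, 5: 4}
HSN_DRUG_TARGET = {1: 69, 2: 291, 3: 103, 4: 5, 5: 1}
HSN_ONCOGENE = {1: 12, 2: 33, 3: 4}
HSN_TUMOUR_SUPPRESSOR = {1: 12, 2: 41, 3: 4, 5: 1}

# Consistently-expressed gene sets (present in >= 99% of a cancer's samples)
# mapped onto HFPIN zones: cancer type -> zone -> count.  Each set's mapped
# size is the sum of its zone counts.
HFPIN_CANCER_EXPRESSED = {
    "breast": {1: 11, 2: 189, 3: 121, 4: 9},
    "cervical": {1: 26, 2: 425, 3: 230, 4: 23, 5: 7},
    "endometrial": {1: 57, 2: 839, 3: 514, 4: 83, 5: 20, 6: 2},
    "fallopian": {1: 49, 2: 715, 3: 446, 4: 67, 5: 14, 6: 1},
    "glioblastoma": {1: 38, 2: 589, 3: 368, 4: 44, 5: 6, 6: 1},
    "glioma": {1: 40, 2: 621, 3: 440, 4: 63, 5: 13, 6: 3},
    "kidney": {1: 14, 2: 331, 3: 193, 4: 23},
    "liver": {1: 29, 2: 402, 3: 247, 4: 33, 5: 4},
    "lung": {1: 19, 2: 314, 3: 175, 4: 22, 5: 2},
    "ovarian": {1: 26, 2: 432, 3: 279, 4: 32, 5: 6},
    "pancreatic": {1: 30, 2: 411, 3: 244, 4: 28, 5: 4},
    "pituitary": {1: 37, 2: 591, 3: 421, 4: 61, 5: 15, 6: 1},
    "rectal": {1: 69, 2: 861, 3: 552, 4: 90, 5: 23, 6: 2},
}

# Zone-2 percentages as printed in the published consistent-expression
# table (row basis: percentage of each set's mapped members).  The printed
# "Average" row averages these printed values unweighted.
HFPIN_CANCER_ZONE2_PRINTED_PERCENT = {
    "breast": 57.2,
    "cervical": 59.7,
    "endometrial": 55.3,
    "fallopian": 55.3,
    "glioblastoma": 56.3,
    "glioma": 57.7,
    "kidney": 59.0,
    "liver": 56.2,
    "lung": 59.0,
    "ovarian": 55.7,
    "pancreatic": 57.3,
    "pituitary": 52.4,
    "rectal": 53.9,
}
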