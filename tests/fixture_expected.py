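"""Hand-computed expected index values for the six worked-fixture subjects.

Every expression below evaluates the published formula directly with plain
Python arithmetic on the fixture's round-number concentrations (insulin and
C-peptide in pmol/l, glucose in mmol/l; HOMA-B1 insulin converted to uU/ml
with 6.945 pmol/l per uU/ml, Matsuda in mg/dl and uU/ml).  This file imports
nothing from the package so it stays an independent oracle.
"""

from math import exp, sqrt

# sid -> (sex_code f=1/m=0, bmi, G, I, CP) copied from the fixture definition
RAW = {
    "ngm_1": (1, 25.0, (5.0, 8.0, 7.0, 6.0),
              (60.0, 300.0, 250.0, 150.0), (600.0, 1800.0, 1700.0, 1500.0)),
    "ngm_2": (0, 27.0, (5.5, 7.5, 6.5, 5.5),
              (50.0, 400.0, 300.0, 100.0), (500.0, 2000.0, 1800.0, 1200.0)),
    "pre_1": (1, 29.0, (6.5, 10.0, 9.5, 9.0),
              (80.0, 320.0, 360.0, 400.0), (800.0, 1600.0, 1800.0, 2000.0)),
    "pre_2": (0, 28.0, (5.8, 9.0, 9.2, 8.0),
              (90.0, 270.0, 300.0, 330.0), (900.0, 1800.0, 2000.0, 2200.0)),
    "t2dm_1": (0, 31.0, (8.0, 13.0, 14.0, 12.0),
               (120.0, 240.0, 300.0, 360.0), (1200.0, 1900.0, 2200.0, 2600.0)),
    "t2dm_2": (1, 32.0, (7.5, 12.0, 13.0, 11.5),
               (100.0, 200.0, 260.0, 320.0), (1000.0, 1700.0, 2000.0, 2400.0)),
}


def _auc(x):
    return 15 * (x[0] + x[1]) + 15 * (x[1] + x[2]) + 30 * (x[2] + x[3])


def _expected_one(sex, bmi, g, i, cp):
    out = {
        "homa_b1": 20 * (i[0] / 6.945) / (g[0] - 3.5),
        "igr_0": i[0] / g[0],
        "cgr_0": cp[0] / g[0],
        "ir_30": i[1] / i[0],
        "cpr_30": cp[1] / cp[0],
        "igi_30": (i[1] - i[0]) / (g[1] - g[0]),
        "igi_mod_30": (i[1] - i[0]) / g[1],
        "cgi_30": (cp[1] - cp[0]) / (g[1] - g[0]),
        "cir_30": i[1] / (g[1] * (g[1] - 3.89)),
        "stumvoll_first": 1283 + 1.829 * i[1] - 138.7 * g[1] + 3.772 * i[0],
        "bigtt_air_0_30_120": exp(
            8.20 + 0.00178 * i[0] + 0.00168 * i[1] - 0.000383 * i[3]
            - 0.314 * g[0] - 0.109 * g[1] + 0.0781 * g[3]
            + 0.180 * sex - 0.032 * bmi),
        "bigtt_air_0_60_120": exp(
            8.19 + 0.00339 * i[0] + 0.00152 * i[2] - 0.000959 * i[3]
            - 0.389 * g[0] - 0.142 * g[2] + 0.164 * g[3]
            + 0.256 * sex + 0.038 * bmi),
        "stumvoll_second": 287 + 0.4164 * i[1] - 26.07 * g[1] + 0.9226 * i[0],
        "ir_120": i[3] / i[0],
        "cpr_120": cp[3] / cp[0],
        "cir_120": i[3] / (g[3] * (g[3] - 3.89)),
        "auc_i_g": _auc(i) / _auc(g),
        "auc_cp_g": _auc(cp) / _auc(g),
        "matsuda": 10000 / sqrt(
            (g[0] * 18.016) * (i[0] / 6.945)
            * (sum(g) / 4 * 18.016) * (sum(i) / 4 / 6.945)),
    }
    # 120 min incremental indices are undefined when G120 == G0
    if g[3] != g[0]:
        out["igi_120"] = (i[3] - i[0]) / (g[3] - g[0])
        out["cgi_120"] = (cp[3] - cp[0]) / (g[3] - g[0])
    else:
        out["igi_120"] = None
        out["cgi_120"] = None
    return out


EXPECTED = {sid: _expected_one(*vals) for sid, vals in RAW.items()}

# spot-frozen literals, hand-summed term by term
assert abs(EXPECTED["ngm_1"]["igi_30"] - 80.0) < 1e-12
assert abs(EXPECTED["ngm_1"]["stumvoll_first"] - 948.42) < 1e-9
assert abs(EXPECTED["ngm_1"]["homa_b1"] - 115.19078473722101) < 1e-9
assert abs(EXPECTED["ngm_1"]["bigtt_air_0_30_120"] - exp(6.15995)) < 1e-9
assert abs(EXPECTED["ngm_1"]["auc_i_g"] - 25650 / 810) < 1e-12
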