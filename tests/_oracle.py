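"""Brute-force FSAm-NPS oracle: literal if-chain scans of the band tables.

Written independently of the package implementation (which uses sorted
searches); used only to cross-check it on random compositions.
"""


def _scan(value, edges):
    pts = 0
    for i, edge in enumerate(edges, start=1):
        if value > edge:
            pts = i
    return pts


def oracle_score(food):
    if food.category == "beverage":
        e = _scan(food.energy_kj, [0, 30, 60, 90, 120, 150, 180, 210, 240, 270])
        s = _scan(food.sugars_g, [0, 1.5, 3, 4.5, 6, 7.5, 9, 10.5, 12, 13.5])
    else:
        e = _scan(food.energy_kj,
                  [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350])
        s = _scan(food.sugars_g,
                  [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45])
    if food.category == "added_fat":
        ratio = 100.0 * food.satfat_g / food.totalfat_g
        sf = 0
        for i, edge in enumerate([10, 16, 22, 28, 34, 40, 46, 52, 58, 64],
                                 start=1):
            if ratio >= edge:
                sf = i
    else:
        sf = _scan(food.satfat_g, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
    so = _scan(food.sodium_mg,
               [90, 180, 270, 360, 450, 540, 630, 720, 810, 900])
    a = e + s + sf + so

    fibre = _scan(food.fibre_g, [0.9, 1.9, 2.8, 3.7, 4.7])
    protein = _scan(food.protein_g, [1.6, 3.2, 4.8, 6.4, 8.0])
    if food.category == "beverage":
        fvln = 10 if food.fvln_pct > 80 else (
            4 if food.fvln_pct > 60 else (2 if food.fvln_pct > 40 else 0))
        fvln_max = 10
    else:
        fvln = 5 if food.fvln_pct > 80 else (
            2 if food.fvln_pct > 60 else (1 if food.fvln_pct > 40 else 0))
        fvln_max = 5

    if a >= 11 and food.category != "cheese" and fvln < fvln_max:
        return a - fibre - fvln
    return a - fibre - protein - fvln
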