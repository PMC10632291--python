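"""Published worked-example data.

``WHEAT_TRAIT_SUMMARY`` holds the published per-trait summary statistics of
a 126-line winter wheat (Mandub x Begra) doubled-haploid population scored
for Septoria tritici blotch resistance traits (percent necrotic leaf area,
percent leaf area with pycnidia, under three fungal isolates and two growth
conditions), heading date and plant height: the minimum, maximum and grand
mean of the line means, together with the published phenotypic total
three-way epistasis estimate ``aaa_p`` rounded to two decimals. They serve
as a worked example for the midrange estimator: ``(min + max)/2 - mean``
reproduces each published ``aaa_p`` to within rounding.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # trait, description, L_min, L_max, lines_mean, aaa_p (published, 2 dp)
    (1, "necrosis % (IPO86036, polytunnel)", 6.67, 96.82, 51.26, 0.48),
    (2, "pycnidia % (IPO86036, polytunnel)", 0.26, 58.57, 27.36, 2.06),
    (3, "necrosis % (IPO86036, growth chamber)", 2.65, 98.26, 45.48, 4.97),
    (4, "pycnidia % (IPO86036, growth chamber)", 0.11, 63.47, 18.54, 13.25),
    (5, "necrosis % (IPO92006, polytunnel)", 1.71, 94.58, 51.57, -3.42),
    (6, "pycnidia % (IPO92006, polytunnel)", 0.0, 47.31, 13.28, 10.37),
    (7, "necrosis % (IPO92006, growth chamber)", 7.33, 72.55, 35.76, 4.18),
    (8, "pycnidia % (IPO92006, growth chamber)", 0.39, 36.46, 13.20, 5.23),
    (9, "necrosis % (IPO88004, polytunnel)", 7.12, 99.8, 80.30, -26.84),
    (10, "pycnidia % (IPO88004, polytunnel)", 0.01, 59.65, 13.87, 15.96),
    (11, "necrosis % (IPO88004, growth chamber)", 5.73, 99.09, 59.98, -7.57),
    (12, "pycnidia % (IPO88004, growth chamber)", 1.13, 88.57, 39.78, 5.07),
    (13, "heading date (IPO86036)", 52.5, 95.0, 73.27, 0.48),
    (14, "heading date (IPO92006)", 52.5, 100.0, 79.15, -2.90),
    (15, "heading date (IPO88004)", 50.0, 105.0, 82.84, -5.34),
    (16, "height (IPO86036)", 150.0, 159.0, 153.07, 1.43),
    (17, "height (IPO92006)", 150.0, 159.0, 153.01, 1.49),
    (18, "height (IPO88004)", 146.0, 160.5, 152.35, 0.90),
]

WHEAT_TRAIT_SUMMARY: pd.DataFrame = pd.DataFrame(
    _ROWS, columns=["trait", "description", "L_min", "L_max",
                    "lines_mean", "aaa_p_published"],
).set_index("trait")
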