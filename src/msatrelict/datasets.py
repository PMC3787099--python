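"""Bundled reference data from the North-African black alder survey.

Two small published tables ship with the package:

* the per-population survey design and diversity summary — 19 North-African
  *Alnus glutinosa* populations (7 Tunisian diploid, 8 Algerian diploid,
  4 Moroccan tetraploid) plus one Scottish post-glacial reference
  population (PGM), with sample sizes, inferred ploidy, the distinct-allele
  histogram columns Nal1a..Nal4a (number of individuals whose maximum
  distinct-allele count at any locus is 1..4), and gene diversity Hs and
  its rarefied version rHs (12 haploid genomes, 11 loci); and
* the reported posterior summary (mode, 5% and 95% quantiles) of the
  demographic parameters under the best-supported divergence scenario.

These power the survey-level analyses (country comparisons, rank tests,
generation-time conversion) and serve as the template for the synthetic
study generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "alder_survey_table",
    "alder_divergence_posterior",
    "SURVEY_REPRESENTATIVES",
]

# code, site, country, altitude (m), N, Nal1a..Nal4a, ploidy, Hs, rHs
_SURVEY_ROWS = [
    ("ZIA", "Cap Serrat", "Tunisia", 10, 30, 0, 30, 0, 0, 2, 0.54, 0.52),
    ("TIT", "Ouchtata", "Tunisia", 82, 30, 0, 30, 0, 0, 2, 0.57, 0.57),
    ("ZLE", "Ain Draham", "Tunisia", 355, 30, 0, 30, 0, 0, 2, 0.59, 0.54),
    ("HLO", "Ain Draham", "Tunisia", 355, 30, 0, 30, 0, 0, 2, 0.57, 0.61),
    ("OAY", "Ain Draham", "Tunisia", 484, 30, 0, 30, 0, 0, 2, 0.58, 0.56),
    ("S18", "Ain Draham", "Tunisia", 750, 30, 0, 30, 0, 0, 2, 0.57, 0.54),
    ("DHA", "Ain Draham", "Tunisia", 395, 31, 0, 31, 0, 0, 2, 0.52, 0.53),
    ("ABE", "Oum Tebboul", "Algeria", 306, 12, 0, 12, 0, 0, 2, 0.48, 0.48),
    ("LAO", "El Kala", "Algeria", 29, 30, 0, 30, 0, 0, 2, 0.51, 0.47),
    ("DER", "El Kala", "Algeria", 30, 30, 0, 30, 0, 0, 2, 0.51, 0.54),
    ("RIG", "Berrihane", "Algeria", 30, 30, 0, 30, 0, 0, 2, 0.54, 0.49),
    ("BCA", "Berrihane", "Algeria", 12, 30, 0, 30, 0, 0, 2, 0.50, 0.49),
    ("BMO", "Ben Mehidi", "Algeria", 6, 30, 0, 30, 0, 0, 2, 0.49, 0.44),
    ("SFA", "Guerbes", "Algeria", 15, 30, 0, 30, 0, 0, 2, 0.54, 0.53),
    ("DAT", "Guerbes", "Algeria", 16, 30, 0, 30, 0, 0, 2, 0.54, 0.54),
    ("BOU", "Bab Taza", "Morocco", 1013, 30, 0, 0, 3, 27, 4, 0.78, 0.76),
    ("OUA", "Chefchaouen", "Morocco", 272, 30, 0, 1, 3, 26, 4, 0.77, 0.70),
    ("MBO", "Chefchaouen", "Morocco", 403, 30, 0, 0, 1, 29, 4, 0.77, 0.70),
    ("TAY", "Tayenza", "Morocco", 974, 28, 0, 0, 1, 27, 4, 0.75, 0.73),
    ("PGM", "Perthshire", "Scotland", 70, 36, 0, 36, 0, 0, 2, 0.67, 0.63),
]

_SURVEY_COLS = [
    "code", "site", "country", "altitude", "n", "nal1a", "nal2a", "nal3a",
    "nal4a", "ploidy", "hs", "rhs",
]

#: the three populations representing the regional gene pools in the
#: demographic inference (Moroccan tetraploid, Tunisian diploid, Scottish
#: post-glacial reference)
SURVEY_REPRESENTATIVES = ("BOU", "TIT", "PGM")

# parameter, prior family, prior min, prior max, posterior mode, Q0.05, Q0.95
_POSTERIOR_ROWS = [
    ("N1", "uniform", 10, 20000, 16600, 10100, 19500),
    ("N2", "uniform", 10, 20000, 1620, 898, 10500),
    ("N3", "uniform", 10, 20000, 12100, 6230, 18400),
    ("Ne", "uniform", 10, 20000, 7140, 2770, 18700),
    ("Ns", "uniform", 10, 20000, 8680, 1550, 18600),
    ("t1", "uniform", 1, 20000, 709, 181, 6120),
    ("t2", "uniform", 1, 20000, 3880, 1850, 9830),
    ("t3b", "uniform", 1, 20000, 8930, 3700, 18300),
    ("t3a", "uniform", 1, 20000, 14400, 4930, 19000),
]

_POSTERIOR_COLS = ["param", "family", "prior_min", "prior_max", "mode", "q05", "q95"]


def alder_survey_table() -> pd.DataFrame:
    """Survey design and published diversity summary (20 populations).

    Columns: population ``code``, ``site``, ``country``, ``altitude`` (m),
    sample size ``n``, the distinct-allele histogram ``nal1a..nal4a``,
    inferred ``ploidy``, and gene diversity ``hs`` / rarefied ``rhs``.
    """
    return pd.DataFrame(_SURVEY_ROWS, columns=_SURVEY_COLS)


def alder_divergence_posterior() -> pd.DataFrame:
    """Published posterior summary of the demographic parameters.

    Effective sizes are in diploid genomes, divergence times in
    generations, under the best-supported scenario (the Moroccan pool
    diverging first, the Tunisian pool most recently).
    """
    return pd.DataFrame(_POSTERIOR_ROWS, columns=_POSTERIOR_COLS)
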