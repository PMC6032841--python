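"""Published summary data of the study population.

The long-term ringing scheme's annual effort and the number of marked
individuals observed per winter season (1990–2015).  These printed
series are the only population-level numbers available alongside the
undeposited resighting data; they anchor sanity checks on sample sizes.
``sample_size`` is blank for 1990, the omitted first season.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ringing_table"]

_ROWS = [
    # year, ringing_effort, sample_size
    (1990, 97, None),
    (1991, 166, 249),
    (1992, 151, 368),
    (1993, 4, 323),
    (1994, 100, 357),
    (1995, 131, 440),
    (1996, None, 343),
    (1997, None, 300),
    (1998, 339, 540),
    (1999, None, 445),
    (2000, 151, 514),
    (2001, 192, 640),
    (2002, 274, 746),
    (2003, 205, 872),
    (2004, 289, 923),
    (2005, 395, 1148),
    (2006, None, 910),
    (2007, 538, 1350),
    (2008, 105, 1162),
    (2009, 189, 1139),
    (2010, None, 709),
    (2011, 168, 704),
    (2012, 232, 804),
    (2013, None, 555),
    (2014, 37, 418),
    (2015, 381, 619),
]


def ringing_table() -> pd.DataFrame:
    """Annual ringing effort and per-season observed sample sizes,
    indexed by season start year."""
    df = pd.DataFrame(_ROWS, columns=["year", "ringing_effort", "sample_size"])
    return df.set_index("year", drop=False)
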