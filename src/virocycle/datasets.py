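"""Published station count table bundled for worked examples and checks.

The table holds virus-like-particle (VLP), prokaryote, and small
phototrophic eukaryote concentrations per compartment (foam, SML, SSW,
precipitation "PRC") for the Skagerrak field campaign (February 2020),
together with the printed SML/SSW enrichment factors and virus-to-host
ratios.  Printed concentrations carry two significant figures, so
statistics recomputed from this table can differ from the printed derived
columns by input rounding; the field-stats functions document the
resulting tolerances.

Values are stored as an inline TSV (plain text, locale-free); ``n.d.``
marks quantities that were not determined.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

# Columns: station, date, then per-specimen concentrations by compartment,
# printed EF(SML/SSW) per specimen, and printed virus-to-prokaryote ratios.
_STATION_COUNTS_TSV = """\
station	date	vlp_foam	vlp_sml	vlp_ssw	vlp_prc	ef_vlp	prok_foam	prok_sml	prok_ssw	prok_prc	ef_prok	euk_foam	euk_sml	euk_ssw	ef_euk	vhr_foam	vhr_sml	vhr_ssw	vhr_prc
1	2020-02-03	n.d.	1.8E+07	1.9E+07	n.d.	0.9	n.d.	7.9E+05	8.0E+05	n.d.	1.0	n.d.	3.3E+03	3.4E+03	1.0	n.d.	22.4	23.5	n.d.
2	2020-02-04	n.d.	1.7E+07	1.7E+07	n.d.	1.0	n.d.	8.5E+05	8.4E+05	n.d.	1.0	n.d.	4.5E+03	4.3E+03	1.0	n.d.	19.4	20.0	n.d.
3	2020-02-06	n.d.	1.7E+07	1.6E+07	n.d.	1.0	n.d.	7.9E+05	7.9E+05	n.d.	1.0	n.d.	2.1E+03	2.1E+03	1.0	n.d.	21.2	20.4	n.d.
4	2020-02-07	1.8E+08	2.6E+07	1.4E+07	n.d.	1.8	3.8E+06	8.0E+05	7.5E+05	n.d.	1.1	1.8E+04	3.4E+03	3.4E+03	1.0	48.4	32.5	19.3	n.d.
12/R	2020-02-10	n.d.	n.d.	n.d.	6.5E+04	n.d.	n.d.	n.d.	n.d.	9.1E+03	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	7.1
5	2020-02-11	n.d.	1.3E+07	1.9E+07	n.d.	0.7	n.d.	8.5E+05	8.7E+05	n.d.	1.0	n.d.	3.2E+03	5.0E+03	0.6	n.d.	15.5	21.7	n.d.
6	2020-02-13	5.0E+07	1.6E+07	1.9E+07	n.d.	0.9	1.3E+06	8.0E+05	7.8E+05	n.d.	1.0	3.4E+03	3.5E+03	3.0E+03	1.2	39.4	20.2	24.4	n.d.
7	2020-02-14	n.d.	1.9E+07	2.0E+07	n.d.	0.9	n.d.	7.0E+05	7.5E+05	n.d.	0.9	n.d.	1.8E+03	3.4E+03	0.5	n.d.	26.8	26.7	n.d.
8	2020-02-15	7.7E+07	3.4E+07	1.9E+07	n.d.	1.8	3.0E+06	9.9E+05	7.6E+05	n.d.	1.3	1.8E+04	6.2E+03	4.2E+03	1.5	25.3	34.2	24.4	n.d.
12/R	2020-02-16	n.d.	n.d.	n.d.	3.7E+04	n.d.	n.d.	n.d.	n.d.	3.9E+03	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	9.5
9	2020-02-19	n.d.	3.1E+07	1.6E+07	n.d.	1.9	n.d.	1.1E+06	8.3E+05	n.d.	1.3	n.d.	5.6E+03	4.5E+03	1.2	n.d.	28.1	19.8	n.d.
12/R	2020-02-21	n.d.	n.d.	n.d.	1.2E+05	n.d.	n.d.	n.d.	n.d.	7.9E+03	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	14.9
12/R	2020-02-22	n.d.	n.d.	n.d.	2.7E+05	n.d.	n.d.	n.d.	n.d.	1.8E+04	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	14.8
10	2020-02-24	5.5E+07	2.0E+07	1.9E+07	n.d.	1.1	1.5E+06	9.2E+05	8.5E+05	n.d.	1.1	6.1E+03	3.9E+03	3.9E+03	1.0	36.2	21.9	22.1	n.d.
11	2020-02-26	n.d.	n.d.	1.5E+07	n.d.	n.d.	n.d.	n.d.	7.0E+05	n.d.	n.d.	n.d.	n.d.	2.1E+03	n.d.	n.d.	n.d.	21.6	n.d.
12/R	2020-02-26	n.d.	n.d.	n.d.	3.4E+05	n.d.	n.d.	n.d.	n.d.	2.7E+03	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	127.8
"""


def station_counts() -> pd.DataFrame:
    """Return the station count table as a DataFrame.

    Numeric columns are float with NaN for ``n.d.``; ``station`` and
    ``date`` stay as strings.  The precipitation rows (station ``12/R``)
    include the snow/rain mixture of 2020-02-26.
    """
    df = pd.read_csv(
        io.StringIO(_STATION_COUNTS_TSV),
        sep="\t",
        dtype={"station": str, "date": str},
        na_values=["n.d."],
    )
    num_cols = [c for c in df.columns if c not in ("station", "date")]
    df[num_cols] = df[num_cols].astype(float)
    return df


def marine_station_counts() -> pd.DataFrame:
    """Rows with any marine measurement (stations 1-11)."""
    df = station_counts()
    return df[df["vlp_prc"].isna()].reset_index(drop=True)


def precipitation_counts() -> pd.DataFrame:
    """The five precipitation rows (rain; last row a snow/rain mixture)."""
    df = station_counts()
    return df[~df["vlp_prc"].isna()].reset_index(drop=True)


def sml_pairs(x_col: str, y_col: str) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete vectors of two columns from the station table."""
    df = station_counts()
    sub = df[[x_col, y_col]].dropna()
    return sub[x_col].to_numpy(), sub[y_col].to_numpy()
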