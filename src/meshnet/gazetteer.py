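"""Country gazetteer: affiliation-string name variants → ISO 3166-1 alpha-3.

Small and deliberately curated rather than exhaustive: it covers the
countries that publish in the health-equity literature plus the spellings
that actually occur at the tail of PubMed affiliation strings.  Callers may
pass their own mapping to :func:`meshnet.corpus.tally_by_country`.
"""

from __future__ import annotations

__all__ = ["COUNTRY_NAMES", "default_gazetteer"]

#: ISO-3 code → canonical English name (used by the synthetic generator).
COUNTRY_NAMES: dict[str, str] = {
    "USA": "USA",
    "CAN": "Canada",
    "AUS": "Australia",
    "GBR": "United Kingdom",
    "BRA": "Brazil",
    "CHE": "Switzerland",
    "COL": "Colombia",
    "LBN": "Lebanon",
    "DEU": "Germany",
    "SWE": "Sweden",
    "FRA": "France",
    "NOR": "Norway",
    "THA": "Thailand",
    "IND": "India",
    "NLD": "Netherlands",
    "ESP": "Spain",
    "DNK": "Denmark",
    "PHL": "Philippines",
    "ARG": "Argentina",
    "CHL": "Chile",
    "CHN": "China",
    "CUB": "Cuba",
    "ETH": "Ethiopia",
    "IRL": "Ireland",
    "ITA": "Italy",
    "JAM": "Jamaica",
    "KEN": "Kenya",
    "MWI": "Malawi",
    "MEX": "Mexico",
    "NPL": "Nepal",
    "PER": "Peru",
    "EGY": "Egypt",
    "SAU": "Saudi Arabia",
    "BEL": "Belgium",
    "TCD": "Chad",
    "ECU": "Ecuador",
    "FIN": "Finland",
    "IRN": "Iran",
    "ISR": "Israel",
    "MLT": "Malta",
    "POL": "Poland",
    "PRT": "Portugal",
    "SWZ": "Eswatini",
    "NGA": "Nigeria",
    "PAK": "Pakistan",
    "RWA": "Rwanda",
    "AUT": "Austria",
    "CRI": "Costa Rica",
    "GRC": "Greece",
    "JOR": "Jordan",
    "ROU": "Romania",
    "TZA": "Tanzania",
    "BGD": "Bangladesh",
    "BWA": "Botswana",
    "BGR": "Bulgaria",
    "COG": "Congo",
    "GMB": "Gambia",
    "IDN": "Indonesia",
    "JPN": "Japan",
    "KAZ": "Kazakhstan",
    "LSO": "Lesotho",
    "MKD": "North Macedonia",
    "MYS": "Malaysia",
    "MMR": "Myanmar",
    "PRI": "Puerto Rico",
    "SGP": "Singapore",
    "SDN": "Sudan",
    "TUR": "Turkey",
    "UGA": "Uganda",
    "KOR": "South Korea",
    "ZAF": "South Africa",
    "NZL": "New Zealand",
}

#: Extra spellings seen in affiliation strings, beyond the canonical names.
_VARIANTS: dict[str, str] = {
    "United States": "USA",
    "United States of America": "USA",
    "U.S.A": "USA",
    "US": "USA",
    "UK": "GBR",
    "U.K": "GBR",
    "Great Britain": "GBR",
    "England": "GBR",
    "Scotland": "GBR",
    "Wales": "GBR",
    "Northern Ireland": "GBR",
    "The Netherlands": "NLD",
    "Holland": "NLD",
    "People's Republic of China": "CHN",
    "PR China": "CHN",
    "P.R. China": "CHN",
    "Republic of Korea": "KOR",
    "Korea": "KOR",
    "Republic of Ireland": "IRL",
    "Islamic Republic of Iran": "IRN",
    "Swaziland": "SWZ",
    "Macedonia": "MKD",
    "Czech Republic": "CZE",
    "Czechia": "CZE",
    "Russia": "RUS",
    "Russian Federation": "RUS",
    "Viet Nam": "VNM",
    "Vietnam": "VNM",
    "Tanzania, United Republic of": "TZA",
    "United Republic of Tanzania": "TZA",
}


def default_gazetteer() -> dict[str, str]:
    """Return the bundled variant → ISO-3 mapping (a fresh copy)."""
    gaz = {name: code for code, name in COUNTRY_NAMES.items()}
    gaz.update(_VARIANTS)
    return gaz
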