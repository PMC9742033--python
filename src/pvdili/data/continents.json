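{
  "AE": "Asian",
  "AF": "Asian",
  "AL": "Europe",
  "AO": "Africa",
  "AR": "South America",
  "AT": "Europe",
  "AU": "Oceania",
  "BA": "Europe",
  "BD": "Asian",
  "BE": "Europe",
  "BF": "Africa",
  "BG": "Europe",
  "BH": "Asian",
  "BJ": "Africa",
  "BO": "South America",
  "BR": "South America",
  "BW": "Africa",
  "BY": "Europe",
  "CA": "North America",
  "CD": "Africa",
  "CG": "Africa",
  "CH": "Europe",
  "CI": "Africa",
  "CL": "South America",
  "CM": "Africa",
  "CN": "Asian",
  "CO": "South America",
  "CR": "North America",
  "CU": "North America",
  "CY": "Europe",
  "CZ": "Europe",
  "DE": "Europe",
  "DK": "Europe",
  "DO": "North America",
  "DZ": "Africa",
  "EC": "South America",
  "EE": "Europe",
  "EG": "Africa",
  "ES": "Europe",
  "ET": "Africa",
  "FI": "Europe",
  "FJ": "Oceania",
  "FR": "Europe",
  "GB": "Europe",
  "GH": "Africa",
  "GR": "Europe",
  "GT": "North America",
  "GY": "South America",
  "HK": "Asian",
  "HN": "North America",
  "HR": "Europe",
  "HU": "Europe",
  "ID": "Asian",
  "IE": "Europe",
  "IL": "Asian",
  "IN": "Asian",
  "IQ": "Asian",
  "IR": "Asian",
  "IS": "Europe",
  "IT": "Europe",
  "JM": "North America",
  "JO": "Asian",
  "JP": "Asian",
  "KE": "Africa",
  "KR": "Asian",
  "KW": "Asian",
  "KZ": "Asian",
  "LB": "Asian",
  "LK": "Asian",
  "LT": "Europe",
  "LU": "Europe",
  "LV": "Europe",
  "LY": "Africa",
  "MA": "Africa",
  "MD": "Europe",
  "MK": "Europe",
  "MT": "Europe",
  "MX": "North America",
  "MY": "Asian",
  "MZ": "Africa",
  "NA": "Africa",
  "NG": "Africa",
  "NI": "North America",
  "NL": "Europe",
  "NO": "Europe",
  "NP": "Asian",
  "NZ": "Oceania",
  "OM": "Asian",
  "PA": "North America",
  "PE": "South America",
  "PG": "Oceania",
  "PH": "Asian",
  "PK": "Asian",
  "PL": "Europe",
  "PT": "Europe",
  "PY": "South America",
  "QA": "Asian",
  "RO": "Europe",
  "RS": "Europe",
  "RU": "Europe",
  "RW": "Africa",
  "SA": "Asian",
  "SD": "Africa",
  "SE": "Europe",
  "SG": "Asian",
  "SI": "Europe",
  "SK": "Europe",
  "SN": "Africa",
  "SR": "South America",
  "SV": "North America",
  "SY": "Asian",
  "TH": "Asian",
  "TN": "Africa",
  "TR": "Asian",
  "TT": "North America",
  "TW": "Asian",
  "TZ": "Africa",
  "UA": "Europe",
  "UG": "Africa",
  "US": "North America",
  "UY": "South America",
  "UZ": "Asian",
  "VE": "South America",
  "VN": "Asian",
  "XK": "Europe",
  "YE": "Asian",
  "ZA": "Africa",
  "ZM": "Africa",
  "ZW": "Africa"
}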