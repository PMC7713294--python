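# Data files

`extinction_coefficients.csv` — editable molar extinction coefficient table
(`species,epsilon_M_cm,wavelength_nm,surrogate_of`). The shipped values are
literature *placeholders* derived from commonly tabulated E1% values; replace
them with vetted coefficients before quantitative use. Tetradehydrolycopene
and dehydro-beta-carotene intentionally have no rows: they are quantified via
the closest-molecule surrogate rule (didehydrolycopene and beta-zeacarotene
respectively, see `carokin.quantify.SURROGATE_RULES`).
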