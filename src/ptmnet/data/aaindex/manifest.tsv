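accession	status	description
ARGP820101	rejected	Hydrophobicity index (Argos et al., 1982)
BIOV880101	selected	Information value for accessibility; average fraction 35% (Biou et al., 1988)
BIOV880102	selected	Information value for accessibility; average fraction 23% (Biou et al., 1988)
BLAS910101	selected	Scaled side chain hydrophobicity values (Black-Mould, 1991)
BLAS910101	rejected	Scaled side chain hydrophobicity values (Black-Mould, 1991)
BULH740101	rejected	Transfer free energy to surface (Bull-Breese, 1974)
FASG760101	rejected	Molecular weight (Fasman, 1976)
HOPA770101	selected	Hydration number (Hopfinger, 1971), Cited by Charton-Charton (1982)
KRIW710101	selected	Side chain interaction parameter (Krigbaum-Rubin, 1971)
KRIW790101	selected	Side chain interaction parameter (Krigbaum-Komoriya, 1979)
KRIW790102	selected	Fraction of site occupied by water (Krigbaum-Komoriya, 1979)
KRIW790103	selected	Side chain volume (Krigbaum-Komoriya, 1979)
LAWE840101	selected	Transfer free energy, CHP/water (Lawson et al., 1984)
OOBM850105	selected	Optimized side chain interaction parameter (Oobatake et al., 1985)
WARP780101	rejected	Average interactions per side chain atom (Warme-Morgan, 1978)
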