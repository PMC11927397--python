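"""Published GMHI species lists (Gupta et al. 2020, Nat. Commun. 11:4635).

Seven health-prevalent ("good") and 43 health-scarce ("bad") species, in
MetaPhlAn underscore naming.  The index consuming these lists treats them as
an external asset; they can be overridden in :class:`dysbio.features.ReferenceAssets`.
"""

GMHI_GOOD_SPECIES: tuple[str, ...] = (
    "Alistipes_senegalensis",
    "Bacteroidales_bacterium_ph8",
    "Bifidobacterium_adolescentis",
    "Bifidobacterium_angulatum",
    "Bifidobacterium_catenulatum",
    "Lachnospiraceae_bacterium_8_1_57FAA",
    "Sutterella_wadsworthensis",
)

GMHI_BAD_SPECIES: tuple[str, ...] = (
    "Anaerotruncus_colihominis",
    "Atopobium_parvulum",
    "Bifidobacterium_dentium",
    "Blautia_producta",
    "candidate_division_TM7_single_cell_isolate_TM7c",
    "Clostridiales_bacterium_1_7_47FAA",
    "Clostridium_asparagiforme",
    "Clostridium_bolteae",
    "Clostridium_citroniae",
    "Clostridium_clostridioforme",
    "Clostridium_hathewayi",
    "Clostridium_nexile",
    "Clostridium_ramosum",
    "Clostridium_symbiosum",
    "Eggerthella_lenta",
    "Erysipelotrichaceae_bacterium_2_2_44A",
    "Flavonifractor_plautii",
    "Fusobacterium_nucleatum",
    "Gemella_morbillorum",
    "Gemella_sanguinis",
    "Granulicatella_adiacens",
    "Holdemania_filiformis",
    "Klebsiella_pneumoniae",
    "Lachnospiraceae_bacterium_1_4_56FAA",
    "Lachnospiraceae_bacterium_2_1_58FAA",
    "Lachnospiraceae_bacterium_3_1_57FAA_CT1",
    "Lachnospiraceae_bacterium_5_1_57FAA",
    "Lachnospiraceae_bacterium_9_1_43BFAA",
    "Lactobacillus_salivarius",
    "Peptostreptococcus_stomatis",
    "Ruminococcaceae_bacterium_D16",
    "Ruminococcus_gnavus",
    "Solobacterium_moorei",
    "Streptococcus_anginosus",
    "Streptococcus_australis",
    "Streptococcus_gordonii",
    "Streptococcus_infantis",
    "Streptococcus_mitis_oralis_pneumoniae",
    "Streptococcus_sanguinis",
    "Streptococcus_vestibularis",
    "Subdoligranulum_sp_4_3_54A2FAA",
    "Subdoligranulum_variabile",
    "Veillonella_atypica",
)

assert len(GMHI_GOOD_SPECIES) == 7
assert len(GMHI_BAD_SPECIES) == 43
assert not set(GMHI_GOOD_SPECIES) & set(GMHI_BAD_SPECIES)
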