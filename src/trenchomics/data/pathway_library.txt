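# Marker-gene / pathway definitions for depth-stratified functional profiling
# of hadal seawater metagenomes (C, N and S cycling panels).
#
# Grammar:  pathway_id (Display Name): step; step; ...
#           step := alternative | alternative | ...
#           alternative := KO + KO + ...   (an enzyme complex; AND-set)
# Lines starting with '#' and blank lines are ignored.
#
# KO assignments are a static curated snapshot (see ko_symbols.tsv); no live
# KEGG queries are performed.

# --- carbon fixation -------------------------------------------------------
cbb_cycle (Calvin-Benson-Bassham cycle markers): K01601+K01602; K00855
rtca_cycle (reverse TCA cycle markers): K15230+K15231 | K15232+K15233
three_hp_bicycle (3-hydroxypropionate bi-cycle markers): K14470; K09709
wood_ljungdahl (Wood-Ljungdahl pathway markers): K00198; K00192+K00195; K14138; K15023

# --- central carbon metabolism --------------------------------------------
glycolysis_specific (glycolysis-specific genes glk/pfk/pyk): K00845; K00850; K00873
gluconeogenesis_specific (gluconeogenesis-specific genes fbp/pck): K03841; K01610
glyoxylate_shunt (glyoxylate shunt): K01637; K01638

# --- oxidative phosphorylation: terminal oxidases --------------------------
oxidase_aa3 (aa3-type cytochrome c oxidase): K02274+K02275+K02276
oxidase_cbb3 (cbb3-type cytochrome c oxidase): K00404+K00405+K00406
oxidase_bd (cytochrome bd ubiquinol oxidase): K00425+K00426
oxidase_qox (cytochrome aa3-600 menaquinol oxidase): K02829+K02830
oxidase_cyo (cytochrome o ubiquinol oxidase): K02297+K02298+K02299

# --- hydrogen and fermentation ---------------------------------------------
hydrogenase_nife (membrane-bound NiFe hydrogenase): K06281+K06282
lactate_fermentation (L-lactate dehydrogenase): K00016
formate_metabolism (formate production and oxidation): K00656; K00123+K00124+K00127
acetate_metabolism (acetate production): K00156 | K00925+K00625
ethanol_metabolism (acetaldehyde and alcohol dehydrogenases): K00128 | K14085 | K00138; K13953 | K00001

# --- nitrogen cycle ---------------------------------------------------------
nitrogen_fixation (nitrogen fixation nifDKH): K02586+K02591+K02588
ammonia_oxidation (ammonia oxidation amoABC): K10944+K10945+K10946
hydroxylamine_oxidation (hydroxylamine oxidation hao): K10535
nitrite_oxidation (nitrite oxidation nxrAB/narGH): K00370+K00371
nitrate_reduction_nar (membrane nitrate reductase narGHI): K00370+K00371+K00374
nitrate_reduction_nap (periplasmic nitrate reductase napAB): K02567+K02568
nitrite_reduction_no (denitrifying nitrite reductase nirK or nirS): K00368 | K15864
nitric_oxide_reduction (nitric oxide reductase norBC): K04561+K02305
nitrous_oxide_reduction (nitrous oxide reductase nosZ): K00376
denitrification (denitrification, nitrate to dinitrogen): K00370+K00371+K00374 | K02567+K02568; K00368 | K15864; K04561+K02305; K00376
dnra (dissimilatory nitrate reduction to ammonium, nirBD or nrfAH): K00362+K00363 | K03385+K15876
urea_transport (urea ABC transporter urtABCDE): K11959+K11960+K11961+K11962+K11963

# --- sulfur cycle -----------------------------------------------------------
assimilatory_sulfate_reduction (assimilatory sulfate reduction): K00958 | K00956+K00957; K00860; K00390; K00380+K00381 | K00392
dissimilatory_sulfate_reduction (dissimilatory sulfate reduction sat/aprAB/dsrAB): K00958; K00394+K00395; K11180+K11181
sox_system (thiosulfate oxidation SOX complex): K17222+K17223+K17224+K17225+K22622+K17226+K17227
thiosulfate_oxidation_tsda (thiosulfate dehydrogenase tsdA): K19713
thiosulfate_oxidation_dox (thiosulfate:quinone oxidoreductase doxAD): K16936+K16937
thiosulfate_reduction_phs (thiosulfate reductase phsABC): K08352+K08353+K08354
sulfite_oxidation_soe (sulfite dehydrogenase soeABC): K21307+K21308+K21309
sulfide_oxidation_fcc (flavocytochrome c sulfide dehydrogenase fccAB): K17229+K17230
sulfur_dioxygenase (sulfur oxygenase/reductase sor): K16952
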