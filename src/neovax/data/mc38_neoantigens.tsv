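# Published MC38 neoantigen set (7 records) encoded by the 7-segment vaccine.
# The source table prints wild-type first with the mutant residue bold; the
# sequence column here is normalized to mutant-first bracket notation [mut/wt].
id	gene	gene_id	sequence
1	CPNE1	26669	DFTGSNGDPSSP[Y/D]SLHYLSPTGVNEY
2	IRGQ	210146	KARDETAALLNSA[V/G]LGAAPLFVPPAD
3	AATF	56321	SKLLSFMAPIDHT[T/A]MSDDARTELFRS
4	REPS1	19707	GRVLELFRAAQL[A/P]NDVVLQIMELCGATR
5	MED12	59024	DIDPSSSVLFE[Y/D]MEKPDFSLFSP
6	DPAGT1	13478	EAGQSLVISASIIVFNL[L/V]ELEGDYR
7	ADPGK	72141	GIPVHLELASMTN[M/R]ELMSSIVHQQVFPT
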