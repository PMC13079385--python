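# rnapal nearest-neighbor parameter table, version 1
# All free energies in kcal/mol at the stated temperature.
#
# Record types (tab separated):
#   scalar  <name>   <value>
#   stack   <XY/ZW>  <dG>    helix stack written 5'-X Y-3' / 3'-Z W-5',
#                            i.e. outer pair X.Z stacked on inner pair Y.W.
#                            Entries not listed are completed by the strand
#                            reversal symmetry XY/ZW == WY'/... handled by the
#                            loader; conflicting duplicates are rejected.
#   hairpin <size>   <dG>    loop initiation penalties, indexed by number of
#   bulge   <size>   <dG>    unpaired bases in the loop; sizes beyond the
#   internal <size>  <dG>    table end are extrapolated logarithmically.
#
scalar	temperature	310.15
scalar	duplex_init	4.09
scalar	terminal_au	0.45
scalar	symmetry_correction	0.43
scalar	min_hairpin	3
scalar	two_loop_max	30
# Watson-Crick / Watson-Crick stacks
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	UA/AU	-1.33
stack	CU/GA	-2.08
stack	CA/GU	-2.11
stack	GU/CA	-2.24
stack	GA/CU	-2.35
stack	CG/GC	-2.36
stack	GG/CC	-3.26
stack	GC/CG	-3.42
# stacks involving G.U wobble pairs
stack	AG/UU	-0.55
stack	AU/UG	-1.36
stack	CG/GU	-1.41
stack	CU/GG	-2.11
stack	GG/CU	-1.53
stack	GU/CG	-2.51
stack	UG/AU	-1.27
stack	UU/AG	-1.00
stack	GG/UU	-0.50
stack	GU/UG	1.29
stack	UG/GU	-0.57
# hairpin loop initiation
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.80
hairpin	7	6.00
hairpin	8	6.20
hairpin	9	6.40
# bulge loop initiation
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
# internal loop initiation (indexed by total unpaired bases on both sides)
internal	2	1.50
internal	3	1.60
internal	4	1.70
internal	5	2.00
internal	6	2.20
internal	7	2.40
internal	8	2.60
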