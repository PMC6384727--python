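# RNA dinucleotide (nearest-neighbor step) thermodynamic parameters.
# enthalpy:    Delta-H  in kcal/mol        (Freier et al. 1986, PNAS 83:9373)
# entropy:     Delta-S  in cal/(mol*K)     (Freier et al. 1986, PNAS 83:9373)
# free_energy: Delta-G at 37 C in kcal/mol (Freier et al. 1986 / Turner rules)
# Values obey nearest-neighbor strand symmetry: v(XY) == v(reverse_complement(XY)).
# Columns are standardized (mean 0, sd 1 over the 16 steps) at load time, so any
# affine rescaling of a column leaves downstream features unchanged.  Users may
# substitute their own table with the same header.
dinucleotide	enthalpy	entropy	free_energy
AA	-6.6	-18.4	-0.9
AC	-10.2	-26.2	-2.1
AG	-7.6	-19.2	-1.7
AU	-5.7	-15.5	-0.9
CA	-10.5	-27.8	-1.8
CC	-12.2	-29.7	-2.9
CG	-8.0	-19.4	-2.0
CU	-7.6	-19.2	-1.7
GA	-13.3	-35.5	-2.3
GC	-14.2	-34.9	-3.4
GG	-12.2	-29.7	-2.9
GU	-10.2	-26.2	-2.1
UA	-8.1	-22.6	-1.1
UC	-13.3	-35.5	-2.3
UG	-10.5	-27.8	-1.8
UU	-6.6	-18.4	-0.9
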