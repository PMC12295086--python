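# External inputs (not redistributable)

Place local copies of the deposited coordinate files and sequences here to
enable acceptance criteria 7–10 and the full `scripts/acceptance.py` report:

    9r4k.pdb 9r4m.pdb 9r4n.pdb 9r4o.pdb 9r4p.pdb 9r4r.pdb 9r4s.pdb
    6ry0.pdb 4c1s.pdb 6shd.pdb 5agd.pdb
    g0s5y9.fasta g0s8a0.fasta

(lower-case names; PDB format for structures, plain FASTA for sequences).
Alternatively set `GLYCOMAP_DATA_DIR` to a directory containing them.
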