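# Hydrogen-bond donor/acceptor atom definitions (version 1).
# One pattern per line: <role><TAB><SMARTS>.  The first atom of each
# match is the flagged atom.  Lines starting with '#' are comments.
#
# Donors: any N-H or O-H.
donor	[#7;!H0]
donor	[#8;!H0]
# Acceptors: aromatic pyridine-type N (not pyrrole-type), nitrile N,
# imine N, amine N not bound to a carbonyl/thiocarbonyl and not part of
# a nitro/N-oxide group; any O except oxygens attached to nitrogen
# (nitro, N-oxide).
acceptor	[n;X2;H0]
acceptor	[N;X1]
acceptor	[N;X2;H0;!$([N]~[#8])]
acceptor	[N;X3;!$([N][C,S]=[O,S,N]);!$([N]~[#8]);!$([N]a)]
acceptor	[#8;!$([#8]~[#7])]
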