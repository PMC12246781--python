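# BLASTN 2.17.0+
# Query: qry|contig1|0
# Database: subjects_db
# Fields: query acc.ver, subject acc.ver, % identity, alignment length, mismatches, gap opens, q. start, q. end, s. start, s. end, evalue, bit score
# 1 hits found
qry|contig1|0	sub-mut|contig1|0	94.112	1019	60	0	1	1019	1	1019	0.0	1426
# BLASTN 2.17.0+
# Query: qry|contig1|1020
# Database: subjects_db
# Fields: query acc.ver, subject acc.ver, % identity, alignment length, mismatches, gap opens, q. start, q. end, s. start, s. end, evalue, bit score
# 1 hits found
qry|contig1|1020	sub-mut|contig1|1020	95.196	1020	49	0	1	1020	1	1020	0.0	1462
# BLASTN 2.17.0+
# Query: qry|contig1|2040
# Database: subjects_db
# Fields: query acc.ver, subject acc.ver, % identity, alignment length, mismatches, gap opens, q. start, q. end, s. start, s. end, evalue, bit score
# 1 hits found
qry|contig1|2040	sub-mut|contig1|2040	94.706	1020	54	0	1	1020	1	1020	0.0	1447
# BLASTN 2.17.0+
# Query: qry|contig1|3060
# Database: subjects_db
# Fields: query acc.ver, subject acc.ver, % identity, alignment length, mismatches, gap opens, q. start, q. end, s. start, s. end, evalue, bit score
# 1 hits found
qry|contig1|3060	sub-mut|contig1|3060	93.824	1020	63	0	1	1020	1	1020	0.0	1418
# BLAST processed 4 queries
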