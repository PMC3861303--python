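housekeeping_synthetic_A	synthetic housekeeping negative control (evenly spaced genes)	gene00010	gene00030	gene00050	gene00070	gene00090	gene00110	gene00130	gene00150	gene00170	gene00190	gene00210	gene00230	gene00250	gene00270	gene00290	gene00310	gene00330	gene00350	gene00370	gene00390	gene00410	gene00430	gene00450	gene00470	gene00490	gene00510	gene00530	gene00550	gene00570	gene00590	gene00610	gene00630	gene00650	gene00670	gene00690	gene00710	gene00730	gene00750	gene00770	gene00790	gene00810	gene00830	gene00850	gene00870	gene00890	gene00910	gene00930	gene00950	gene00970	gene00990	gene01010	gene01030	gene01050	gene01070	gene01090
housekeeping_synthetic_B	synthetic housekeeping negative control (evenly spaced genes)	gene01110	gene01130	gene01150	gene01170	gene01190	gene01210	gene01230	gene01250	gene01270	gene01290	gene01310	gene01330	gene01350	gene01370	gene01390	gene01410	gene01430	gene01450	gene01470	gene01490	gene01510	gene01530	gene01550	gene01570	gene01590	gene01610	gene01630	gene01650	gene01670	gene01690	gene01710	gene01730	gene01750	gene01770	gene01790	gene01810	gene01830	gene01850	gene01870	gene01890	gene01910	gene01930	gene01950	gene01970	gene01990	gene02010	gene02030	gene02050	gene02070	gene02090	gene02110	gene02130	gene02150	gene02170	gene02190
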