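# Synthetic hemoglobin molar extinction spectra (NOT measured data).
# Smooth Gaussian-mixture approximation to the canonical visible-band
# oxy/deoxy-hemoglobin spectra: HbO2 Q-band doublet at 542/577 nm,
# Hb single broad band at 556 nm, Soret flank below 500 nm, red window
# above 600 nm. Units: cm^-1 M^-1, base-10 (decadic) convention.
# Model: eps_hbo = 300 + G(450,42,62000) + G(560,28,30000) + G(542,9,26000) + G(577,9,25000)
#        eps_hbr = 600 + G(450,40,80000) + G(556,30,39000) + G(556,12,15000)
#        with G(c,s,a)(l) = a*exp(-((l-c)/s)^2), l in nm.
# version: 1
wavelength_nm	eps_hbo	eps_hbr
450	62300.0	80600.1
451	62264.9	80550.2
452	62159.6	80400.5
453	61984.5	80151.6
454	61740.2	79804.4
455	61427.5	79360.2
456	61047.5	78820.7
457	60601.5	78187.9
458	60090.9	77464.1
459	59517.5	76651.9
460	58883.1	75754.4
461	58189.9	74774.8
462	57440.0	73716.6
463	56635.9	72583.6
464	55780.3	71379.7
465	54875.7	70109.1
466	53925.1	68776.3
467	52931.3	67385.7
468	51897.5	65942.1
469	50826.7	64450.1
470	49722.1	62914.6
471	48586.9	61340.5
472	47424.4	59732.8
473	46237.9	58096.4
474	45030.6	56436.3
475	43805.8	54757.3
476	42566.8	53064.3
477	41316.8	51362.1
478	40058.8	49655.3
479	38796.1	47948.6
480	37531.7	46246.3
481	36268.4	44552.8
482	35009.2	42872.2
483	33756.7	41208.6
484	32513.8	39565.8
485	31282.8	37947.5
486	30066.2	36357.1
487	28866.4	34798.0
488	27685.5	33273.3
489	26525.6	31786.0
490	25388.7	30338.7
491	24276.5	28934.2
492	23190.9	27574.9
493	22133.4	26262.9
494	21105.5	25000.5
495	20108.6	23789.5
496	19144.0	22631.8
497	18213.0	21529.0
498	17316.6	20482.7
499	16455.8	19494.3
500	15631.8	18565.1
501	14845.4	17696.3
502	14097.4	16889.0
503	13388.8	16144.2
504	12720.2	15462.8
505	12092.4	14845.7
506	11506.3	14293.6
507	10962.5	13807.1
508	10461.7	13386.9
509	10004.6	13033.5
510	9592.0	12747.2
511	9224.5	12528.4
512	8902.9	12377.2
513	8628.0	12293.7
514	8400.7	12277.9
515	8221.8	12329.7
516	8092.7	12448.6
517	8015.1	12634.2
518	7991.0	12885.8
519	8024.0	13202.6
520	8118.7	13583.7
521	8282.0	14027.7
522	8523.8	14533.4
523	8857.5	15099.1
524	9301.1	15723.4
525	9877.7	16404.4
526	10615.5	17140.4
527	11547.3	17929.8
528	12708.8	18771.0
529	14135.8	19662.8
530	15860.0	20604.3
531	17903.2	21595.2
532	20272.1	22635.8
533	22951.6	23727.0
534	25900.5	24870.6
535	29048.4	26068.9
536	32296.8	27324.9
537	35523.1	28641.9
538	38589.7	30022.9
539	41354.7	31470.7
540	43686.8	32986.4
541	45477.9	34569.6
542	46655.8	36216.8
543	47191.9	37921.2
544	47103.9	39671.5
545	46453.4	41451.8
546	45337.6	43241.1
547	43877.7	45013.5
548	42205.5	46738.5
549	40449.4	48381.9
550	38723.0	49907.2
551	37117.0	51277.1
552	35694.6	52455.4
553	34491.6	53408.7
554	33519.1	54108.9
555	32769.1	54534.3
556	32220.7	54671.3
557	31847.5	54515.3
558	31623.2	54070.7
559	31526.9	53350.8
560	31546.7	52376.9
561	31680.9	51177.1
562	31938.7	49784.3
563	32338.0	48234.4
564	32902.4	46564.4
565	33656.1	44810.6
566	34617.8	43006.8
567	35794.4	41183.1
568	37174.6	39365.1
569	38723.4	37573.3
570	40379.5	35823.4
571	42055.2	34125.9
572	43641.1	32487.3
573	45013.4	30910.6
574	46045.2	29395.7
575	46619.9	27940.8
576	46643.6	26542.6
577	46057.2	25197.3
578	44843.6	23901.1
579	43030.2	22650.1
580	40686.5	21441.2
581	37916.0	20272.0
582	34845.5	19140.5
583	31610.8	18045.7
584	28344.6	16986.8
585	25164.5	15963.9
586	22165.1	14977.0
587	19413.9	14026.7
588	16950.4	13113.5
589	14788.9	12237.9
590	12922.7	11400.6
591	11330.4	10602.0
592	9981.1	9842.3
593	8840.2	9121.6
594	7872.7	8439.9
595	7046.6	7796.8
596	6334.2	7191.9
597	5712.7	6624.4
598	5164.0	6093.6
599	4674.6	5598.5
600	4234.3	5137.9
601	3835.6	4710.6
602	3473.2	4315.3
603	3143.1	3950.6
604	2842.3	3614.9
605	2568.3	3306.9
606	2319.1	3024.9
607	2092.9	2767.5
608	1888.1	2533.1
609	1703.2	2320.2
610	1536.7	2127.4
611	1387.2	1953.2
612	1253.4	1796.2
613	1133.9	1655.0
614	1027.5	1528.5
615	933.1	1415.3
616	849.5	1314.3
617	775.7	1224.5
618	710.8	1144.7
619	653.9	1074.1
620	604.0	1011.7
621	560.5	956.7
622	522.7	908.4
623	489.9	866.0
624	461.5	829.0
625	437.0	796.6
626	415.9	768.5
627	397.8	744.1
628	382.4	722.9
629	369.1	704.6
630	357.9	688.8
631	348.4	675.3
632	340.3	663.7
633	333.5	653.7
634	327.8	645.2
635	323.0	638.0
636	318.9	631.8
637	315.6	626.6
638	312.8	622.2
639	310.5	618.5
640	308.5	615.4
641	307.0	612.7
642	305.7	610.5
643	304.6	608.7
644	303.7	607.1
645	303.0	605.9
646	302.4	604.8
647	301.9	603.9
648	301.5	603.2
649	301.2	602.6
650	301.0	602.1
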